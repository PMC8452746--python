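"""End-to-end deconvolution pipeline over one patient's segment data.

Wires the stages together: event unification -> missing-MCF handling ->
stem detection -> MCF-profile pre-clustering -> space allocation across
biopsies -> event matrix -> (optionally) MP/ML phylogenies with
contradiction annotation.  All tunables live in :class:`RunConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import pandas as pd

from . import clustering, deconvolution, event_unification, phylogeny
from .genome import GenomeModel, load_genome
from .segment_io import AlterationRecord, RulesMatrix

__all__ = ["RunConfig", "RunResult", "run_deconvolution"]


@dataclass
class RunConfig:
    """All tunables of a deconvolution run (serialized into the report)."""

    co_ev: float = event_unification.DEFAULT_CO_EV
    stem_threshold: float = event_unification.DEFAULT_STEM_THRESHOLD
    arm_tolerance: float = event_unification.DEFAULT_ARM_TOLERANCE
    eps: float = clustering.DEFAULT_EPS
    min_pts: int = 1
    scale: str = "percent"
    precluster: bool = True
    tol_overlap: float = deconvolution.DEFAULT_TOL_OVERLAP
    method: str = "both"  # {"mp", "ml", "both", "none"}
    ratchet_iters: int = 50
    nni_moves: bool = False
    seed: int = 0
    user_stem: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.method not in {"mp", "ml", "both", "none"}:
            raise ValueError(f"unknown method {self.method!r}")
        if self.eps <= 0 or self.co_ev < 0 or not 0 < self.stem_threshold <= 100:
            raise ValueError("invalid configuration values")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["user_stem"] = list(self.user_stem)
        return d


@dataclass
class RunResult:
    catalog: event_unification.EventCatalog
    clusters: clustering.ClusterSet
    tree: deconvolution.CloneTree
    event_matrix: pd.DataFrame
    fractions: pd.DataFrame
    mp: phylogeny.Phylogeny | None = None
    ml: phylogeny.Phylogeny | None = None
    contradictions_mp: phylogeny.ContradictionReport | None = None
    contradictions_ml: phylogeny.ContradictionReport | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def stem_only(self) -> bool:
        """True when every cell shares one genomic profile (no subclonal
        events): an event matrix exists but a phylogeny is uninformative."""
        return len(self.clusters.subclonal_ids()) == 0


def run_deconvolution(
    records: Sequence[AlterationRecord],
    biopsies: Sequence[str],
    config: RunConfig | None = None,
    rules: RulesMatrix | None = None,
    genome: GenomeModel | None = None,
) -> RunResult:
    """Run the full pipeline on one patient's alteration records."""
    config = config or RunConfig()
    genome = genome or load_genome()
    warnings: list[str] = []

    catalog = event_unification.unify_events(
        records, co_ev=config.co_ev, stem_threshold=config.stem_threshold
    )
    catalog, w = event_unification.impute_missing(
        catalog, biopsies, user_stem=config.user_stem, threshold=config.stem_threshold
    )
    warnings.extend(catalog.warnings)
    event_unification.annotate_scopes(catalog, genome, config.arm_tolerance)
    T = event_unification.build_mcf_matrix(catalog, biopsies)

    if config.precluster:
        clusters = clustering.dbscan_clusters(
            T, eps=config.eps, min_pts=config.min_pts, scale=config.scale,
            catalog=catalog,
        )
    else:
        clusters = clustering.singleton_clusters(T, catalog=catalog)
    Z = clustering.cluster_size_matrix(clusters, T)

    tree = deconvolution.integrate_across_biopsies(
        Z, clusters, rules=rules, tol_overlap=config.tol_overlap
    )
    warnings.extend(tree.warnings)
    E = deconvolution.build_event_matrix(tree)
    result = RunResult(
        catalog=catalog,
        clusters=clusters,
        tree=tree,
        event_matrix=E,
        fractions=tree.fractions,
        warnings=warnings,
    )

    if config.method != "none" and not result.stem_only:
        if config.method in {"mp", "both"}:
            result.mp = phylogeny.mp_tree(
                E, ratchet_iters=config.ratchet_iters, seed=config.seed
            )
            result.contradictions_mp = phylogeny.detect_contradictions(
                result.mp, E, catalog
            )
        if config.method in {"ml", "both"}:
            result.ml = phylogeny.ml_tree(E, nni_moves=config.nni_moves)
            result.contradictions_ml = phylogeny.detect_contradictions(
                result.ml, E, catalog
            )
    return result
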