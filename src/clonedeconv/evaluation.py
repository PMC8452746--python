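"""Cohort-level analytics over batches of segment files.

For each tumor the full pipeline is run and the MP and ML trees are
compared: tree statistics (branch count, total branch length, stem
length), whether the two topologies are identical, and how many
parallel-evolution (PLC) and back-mutation (BMC) contradictions remain
before and after exempting whole-chromosome/arm events.  Group
comparisons use the two-sided Mann–Whitney U test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
from scipy import stats

from .phylogeny import compare_topologies, tree_stats
from .pipeline import RunConfig, RunResult, run_deconvolution
from .segment_io import read_segment_table

__all__ = ["CohortReport", "run_cohort", "rank_test"]


@dataclass
class CohortReport:
    table: pd.DataFrame
    results: dict[str, RunResult] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)

    def fraction_differing(self) -> float:
        """Fraction of tree-bearing tumors whose MP and ML topologies differ."""
        t = self.table[self.table["has_tree"]]
        if t.empty:
            return float("nan")
        return float((~t["topologies_identical"]).mean())


def _summarize(tumor_id: str, result: RunResult) -> dict:
    row: dict = {
        "tumor_id": tumor_id,
        "n_biopsies": result.fractions.shape[1],
        "n_subclones": len(result.tree.order),
        "stem_only": result.stem_only,
        "has_tree": result.mp is not None and result.ml is not None,
        "topologies_identical": None,
        "plc": 0,
        "bmc": 0,
        "contradictions_after_exemption": 0,
    }
    if result.mp is not None:
        s = tree_stats(result.mp)
        row.update(
            mp_branches=s.n_branches,
            mp_total_length=s.total_branch_length,
            mp_stem_length=s.stem_length,
        )
    if result.ml is not None:
        s = tree_stats(result.ml)
        row.update(
            ml_branches=s.n_branches,
            ml_total_length=s.total_branch_length,
            ml_stem_length=s.stem_length,
        )
    if row["has_tree"]:
        row["topologies_identical"] = compare_topologies(result.mp, result.ml)
        rep = result.contradictions_mp
        row["plc"] = rep.counts()["PLC"]
        row["bmc"] = rep.counts()["BMC"]
        row["contradictions_after_exemption"] = len(rep.non_exempt())
    return row


def run_cohort(
    segment_files: Sequence[str | Path],
    config: RunConfig | None = None,
    tumor_ids: Sequence[str] | None = None,
) -> CohortReport:
    """Run the pipeline on every segment file; per-tumor failures are
    logged and the cohort continues.

    Tumors whose cells all share one genomic profile (stem only) yield
    an event matrix but are flagged and excluded from tree statistics.
    """
    if not segment_files:
        raise ValueError("need at least one segment file")
    config = config or RunConfig()
    ids = list(tumor_ids) if tumor_ids else [Path(f).stem for f in segment_files]
    rows, results, errors = [], {}, {}
    for tid, path in zip(ids, segment_files):
        try:
            records, matrix = read_segment_table(path)
            result = run_deconvolution(records, matrix.biopsies, config=config)
            results[tid] = result
            rows.append(_summarize(tid, result))
        except Exception as exc:  # keep the cohort going
            errors[tid] = str(exc)
    return CohortReport(table=pd.DataFrame(rows), results=results, errors=errors)


def rank_test(group1: Sequence[float], group2: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann–Whitney U with tie correction: (U, p).

    Exact null distribution for combined n <= 20 without ties, normal
    approximation with continuity and tie correction otherwise.
    """
    if len(group1) == 0 or len(group2) == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(group1, group2, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)
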