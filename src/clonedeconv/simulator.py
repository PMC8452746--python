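"""Stochastic 3D-lattice tumor growth and virtual bulk biopsies.

The growth model is deliberately minimal: it is not meant to mimic
tumor biology, only to produce a spatially structured random mixture of
genotypes whose true clonal composition is known.  One founder cell
carrying a single aberration (the stem event) sits on an integer
lattice where every cell has 26 neighbors and no two cells share a
position.  At each step a random cell with at least one free neighbor
divides; with probability ``mut_prob`` the newly placed daughter gains
one additional random copy-number aberration (chromosome, breakpoints
and type all drawn uniformly within the genome model), otherwise the
daughter is identical to the mother.  Growth stops at ``n_cells``.

Virtual biopsies are balls of radius 2 lattice units whose centers are
drawn uniformly in the tumor's bounding box, accepted when their
distance from the box center falls in [r_mean/2, r_mean] with r_mean
the mean of the six absolute coordinate half-extents — a mid-shell
band avoiding both the core and the empty corners.  Each biopsy yields
per-mutation MCFs (percent of member cells carrying the mutation), a
segment file in the standard dialect, and the ground-truth lineage of
every mutation for scoring.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import GenomeModel, load_genome
from .pipeline import RunConfig, RunResult, run_deconvolution
from .segment_io import AlterationRecord

__all__ = [
    "SimMutation",
    "SimTumor",
    "VirtualBiopsy",
    "random_cna",
    "grow_tumor",
    "sample_biopsies",
    "segment_records",
    "allocation_accuracy",
    "fig4_experiment",
]

_NEIGHBORS = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]

_CNA_TYPES = ("gain", "loss", "cnni")


@dataclass(frozen=True)
class SimMutation:
    id: int
    chrom: str
    start_bp: int
    end_bp: int
    alt_type: str


@dataclass
class SimTumor:
    """Grown tumor: cell positions, per-cell genotype ids, and the
    genotype tree (each genotype = parent genotype + one mutation)."""

    positions: list[tuple[int, int, int]]
    cell_genotype: list[int]
    genotype_parent: dict[int, int]  # genotype id -> parent genotype id (-1 for founder)
    mutations: dict[int, SimMutation]  # mutation id == genotype id it created
    mut_prob: float
    seed: int
    _lineage_cache: dict[int, frozenset] = field(default_factory=dict, repr=False)

    @property
    def n_cells(self) -> int:
        return len(self.positions)

    @property
    def founder_mutation(self) -> int:
        return 0

    def lineage(self, genotype_id: int) -> frozenset:
        """All mutation ids carried by cells of this genotype."""
        if genotype_id in self._lineage_cache:
            return self._lineage_cache[genotype_id]
        chain: list[int] = []
        g = genotype_id
        while g != -1 and g not in self._lineage_cache:
            chain.append(g)
            g = self.genotype_parent[g]
        base = self._lineage_cache.get(g, frozenset())
        acc = set(base)
        for gid in reversed(chain):
            acc.add(gid)
            self._lineage_cache[gid] = frozenset(acc)
        return self._lineage_cache[genotype_id]

    def mutation_lineage(self, mutation_id: int) -> frozenset:
        """Mutations in the genotype where this mutation arose (itself
        plus its ancestors) — the truth against which an inferred
        genotype is scored."""
        return self.lineage(mutation_id)

    def subclonal_mutation_count(self) -> int:
        return len(self.mutations) - 1


@dataclass
class VirtualBiopsy:
    name: str
    center: tuple[float, float, float]
    radius: float
    cells: list[int]
    mcf: dict[int, float]  # mutation id -> percent of member cells


def random_cna(genome: GenomeModel, rng: random.Random, mut_id: int) -> SimMutation:
    """Uniform random copy-number aberration within chromosome bounds."""
    chrom = rng.choice(genome.names)
    length = genome[chrom].length
    a = rng.randint(1, length)
    b = rng.randint(1, length)
    while b == a:
        b = rng.randint(1, length)
    start, end = min(a, b), max(a, b)
    return SimMutation(
        id=mut_id, chrom=chrom, start_bp=start, end_bp=end,
        alt_type=rng.choice(_CNA_TYPES),
    )


def grow_tumor(
    n_cells: int = 40_000,
    mut_prob: float | None = None,
    mut_target: int | None = None,
    genome: GenomeModel | None = None,
    seed: int = 0,
) -> SimTumor:
    """Grow a lattice tumor from one founder cell.

    ``mut_prob`` is the per-division probability that the new daughter
    acquires one extra aberration; alternatively ``mut_target`` sets
    mut_prob = mut_target / n_cells, so roughly that many subclonal
    alterations arise over the whole growth.
    """
    if (mut_prob is None) == (mut_target is None):
        raise ValueError("give exactly one of mut_prob / mut_target")
    if mut_prob is None:
        mut_prob = mut_target / n_cells
    if not 0.0 <= mut_prob <= 1.0:
        raise ValueError("mut_prob must be in [0, 1]")
    genome = genome or load_genome()
    rng = random.Random(seed)

    founder = random_cna(genome, rng, 0)
    positions: list[tuple[int, int, int]] = [(0, 0, 0)]
    occupied: dict[tuple[int, int, int], int] = {(0, 0, 0): 0}
    cell_genotype: list[int] = [0]
    genotype_parent: dict[int, int] = {0: -1}
    mutations: dict[int, SimMutation] = {0: founder}

    frontier: list[int] = [0]  # cells that may still have a free neighbor
    while len(positions) < n_cells:
        if not frontier:
            raise RuntimeError("lattice jammed: no cell has a free neighbor")
        i = rng.randrange(len(frontier))
        ci = frontier[i]
        x, y, z = positions[ci]
        free = [
            (x + dx, y + dy, z + dz)
            for dx, dy, dz in _NEIGHBORS
            if (x + dx, y + dy, z + dz) not in occupied
        ]
        if not free:
            frontier[i] = frontier[-1]
            frontier.pop()
            continue
        pos = free[rng.randrange(len(free))]
        idx = len(positions)
        positions.append(pos)
        occupied[pos] = idx
        frontier.append(idx)
        if rng.random() < mut_prob:
            mid = len(mutations)
            mutations[mid] = random_cna(genome, rng, mid)
            genotype_parent[mid] = cell_genotype[ci]
            cell_genotype.append(mid)
        else:
            cell_genotype.append(cell_genotype[ci])
    return SimTumor(
        positions=positions,
        cell_genotype=cell_genotype,
        genotype_parent=genotype_parent,
        mutations=mutations,
        mut_prob=mut_prob,
        seed=seed,
    )


def sample_biopsies(
    tumor: SimTumor,
    n_biopsies: int,
    radius: float = 2.0,
    seed: int = 0,
    max_retries: int = 1000,
) -> list[VirtualBiopsy]:
    """Draw spherical virtual biopsies from the mid-shell band."""
    if not 1 <= n_biopsies:
        raise ValueError("n_biopsies must be >= 1")
    rng = random.Random(seed)
    pos = np.array(tumor.positions, dtype=float)
    lo, hi = pos.min(axis=0), pos.max(axis=0)
    center = (lo + hi) / 2.0
    half = (hi - lo) / 2.0
    r_mean = float(np.mean(np.concatenate([half, half])))  # six absolute half-extents
    occupied = {p: i for i, p in enumerate(tumor.positions)}

    biopsies: list[VirtualBiopsy] = []
    for k in range(n_biopsies):
        members: list[int] = []
        bc = None
        for _ in range(max_retries):
            offset = np.array([rng.uniform(-h, h) for h in half])
            r = float(np.linalg.norm(offset))
            if not (r_mean / 2.0 <= r <= r_mean):
                continue
            bc = center + offset
            members = _cells_in_ball(occupied, bc, radius)
            if members:
                break
        if not members:
            raise RuntimeError(
                f"could not draw a non-empty biopsy after {max_retries} tries"
            )
        counts: dict[int, int] = {}
        for ci in members:
            for m in tumor.lineage(tumor.cell_genotype[ci]):
                counts[m] = counts.get(m, 0) + 1
        mcf = {m: 100.0 * c / len(members) for m, c in counts.items()}
        biopsies.append(
            VirtualBiopsy(
                name=f"P{k + 1}",
                center=tuple(float(v) for v in bc),
                radius=radius,
                cells=members,
                mcf=mcf,
            )
        )
    return biopsies


def _cells_in_ball(
    occupied: dict[tuple[int, int, int], int],
    center: np.ndarray,
    radius: float,
) -> list[int]:
    cx, cy, cz = center
    keys = occupied.keys()
    # scan the ball's bounding cube clipped to the occupied lattice extent
    los = [min(k[d] for k in keys) for d in range(3)]
    his = [max(k[d] for k in keys) for d in range(3)]
    out = []
    r2 = radius * radius
    for x in range(max(math.floor(cx - radius), los[0]),
                   min(math.ceil(cx + radius), his[0]) + 1):
        for y in range(max(math.floor(cy - radius), los[1]),
                       min(math.ceil(cy + radius), his[1]) + 1):
            for z in range(max(math.floor(cz - radius), los[2]),
                           min(math.ceil(cz + radius), his[2]) + 1):
                if (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= r2:
                    idx = occupied.get((x, y, z))
                    if idx is not None:
                        out.append(idx)
    return out


def segment_records(
    tumor: SimTumor, biopsies: Sequence[VirtualBiopsy]
) -> tuple[list[AlterationRecord], list[str]]:
    """Segment-file records for every mutation detected in >= 1 biopsy."""
    names = [b.name for b in biopsies]
    detected = sorted({m for b in biopsies for m in b.mcf})
    records = []
    for m in detected:
        mut = tumor.mutations[m]
        records.append(
            AlterationRecord(
                event_id=f"m{m}",
                chrom=mut.chrom,
                start_bp=mut.start_bp,
                end_bp=mut.end_bp,
                alt_type=mut.alt_type,
                label="stem" if m == tumor.founder_mutation else "",
                source="snp_array",
                mcf={b.name: float(b.mcf.get(m, 0.0)) for b in biopsies},
            )
        )
    return records, names


def allocation_accuracy(
    result: RunResult,
    tumor: SimTumor,
    exclude_single_biopsy: bool = False,
) -> tuple[int, int]:
    """(correct, evaluated) allocation counts against ground truth.

    A detected mutation is correctly allocated when the full genotype
    of the subclone it was assigned to equals the true lineage set of
    the genotype in which it arose, both restricted to detected
    mutations.  With ``exclude_single_biopsy`` the comparison is
    restricted to mutations whose MCF is nonzero in more than one
    biopsy.
    """
    detected_ids = [e for e in result.event_matrix.index]
    detected = {int(e[1:]) for e in detected_ids}
    if exclude_single_biopsy:
        keep = set()
        for rec in result.catalog.unique_events:
            n_pos = sum(1 for v in rec.mcf.values() if v is not None and v > 0)
            if n_pos > 1:
                keep.add(int(rec.event_id[1:]))
        eval_set = keep
    else:
        eval_set = detected

    correct = 0
    evaluated = 0
    scored = detected & eval_set
    for m in sorted(scored):
        cluster = result.clusters.cluster_of(f"m{m}")
        inferred = {int(e[1:]) for e in result.tree.genotype(cluster)}
        truth = set(tumor.mutation_lineage(m)) & detected
        if exclude_single_biopsy:
            inferred &= eval_set
            truth &= eval_set
        evaluated += 1
        if inferred == truth:
            correct += 1
    return correct, evaluated


def fig4_experiment(
    mut_targets: Sequence[int] = (15, 50, 100),
    biopsy_counts: Sequence[int] = tuple(range(1, 11)),
    reps: int = 3,
    n_cells: int = 40_000,
    radius: float = 2.0,
    seed: int = 0,
    config: RunConfig | None = None,
    genome: GenomeModel | None = None,
) -> pd.DataFrame:
    """Full factorial allocation-accuracy sweep on simulated tumors.

    One tumor is grown per mutation target; for each biopsy count,
    ``reps`` independent sets of biopsies are drawn (repeated
    measurements on the same tumor), the deconvolution is run on each
    resulting segment file, and the proportion of detected alterations
    correctly allocated is recorded — both over all events and
    excluding those found in a single biopsy.
    """
    genome = genome or load_genome()
    base = np.random.SeedSequence(seed)
    n_seeds = len(mut_targets) * (1 + reps * len(biopsy_counts)) + 8
    sub_seeds = base.generate_state(n_seeds).astype(np.int64) % (2**31 - 1)
    seed_iter = iter(sub_seeds.tolist())
    cfg = config or RunConfig(method="none")

    rows = []
    for target in mut_targets:
        tumor = grow_tumor(
            n_cells=n_cells, mut_target=target, genome=genome,
            seed=int(next(seed_iter)),
        )
        for nb in biopsy_counts:
            for rep in range(reps):
                bset = sample_biopsies(
                    tumor, nb, radius=radius, seed=int(next(seed_iter))
                )
                records, names = segment_records(tumor, bset)
                result = run_deconvolution(records, names, config=cfg, genome=genome)
                c_all, n_all = allocation_accuracy(result, tumor, False)
                c_multi, n_multi = allocation_accuracy(result, tumor, True)
                rows.append(
                    {
                        "mut_target": target,
                        "rep": rep,
                        "n_biopsies": nb,
                        "n_detected": n_all,
                        "n_correct": c_all,
                        "prop_all": c_all / n_all if n_all else np.nan,
                        "n_detected_multi": n_multi,
                        "n_correct_multi": c_multi,
                        "prop_multi": c_multi / n_multi if n_multi else np.nan,
                    }
                )
    return pd.DataFrame(rows)
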