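"""Mutated clone fraction (MCF) computation from sequencing summaries.

For a point mutation observed at variant allele frequency VAF in a
sample of tumor cell fraction (purity) TCF, with allele-specific copy
numbers CN_mut / CN_wt at the locus and M mutated allele copies, the
mean sample fraction is

    MSF = VAF * ((CN_mut + CN_wt) * TCF + 2 * (1 - TCF)) / M

and the mutated clone fraction, the proportion of *tumor* cells
carrying the mutation, is

    MCF = 100 * MSF / TCF   [percent]

TCF itself is estimated per sample from the VAF distribution: among the
local maxima of a kernel density estimate of the VAFs, the mode closest
to 0.5 is taken, and TCF = 2x its location (a clonal heterozygous
mutation in a diploid tumor has VAF = TCF/2).
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal, stats

__all__ = [
    "MutationObservation",
    "estimate_tcf",
    "compute_msf",
    "compute_mcf",
    "qc_filter",
]


@dataclass
class MutationObservation:
    """Per-mutation, per-sample quantities needed for MCF computation."""

    vaf: float
    cn_mutant: int = 1
    cn_wildtype: int = 1
    multiplicity_m: int = 1
    read_depth: int | None = None
    total_coverage: int | None = None
    diploid: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"VAF {self.vaf} outside [0, 1]")
        if self.cn_mutant < 0 or self.cn_wildtype < 0:
            raise ValueError("allele copy numbers must be >= 0")
        if self.cn_mutant + self.cn_wildtype < 1:
            raise ValueError("total copy number must be >= 1")


def estimate_tcf(
    vafs: Sequence[float], min_mutations: int = 10, grid_size: int = 512
) -> float:
    """Tumor cell fraction from the VAF density.

    Gaussian KDE (Silverman bandwidth) on VAFs in (0, 1]; among local
    maxima of the density the one closest to VAF 0.5 is selected and
    TCF = 2 x its location, clipped into (0, 1].
    """
    vafs = np.asarray(list(vafs), dtype=float)
    if np.any((vafs < 0) | (vafs > 1)):
        raise ValueError("VAFs must lie in [0, 1]")
    vafs = vafs[vafs > 0]
    if vafs.size < min_mutations:
        raise ValueError(
            f"only {vafs.size} usable VAFs (< {min_mutations}); "
            "supply the TCF manually"
        )
    if np.allclose(vafs, vafs[0]):
        return float(np.clip(2 * vafs[0], 0.0, 1.0))
    kde = stats.gaussian_kde(vafs, bw_method="silverman")
    grid = np.linspace(0.0, 1.0, grid_size)
    dens = kde(grid)
    peaks, _ = signal.find_peaks(dens, height=0.01 * dens.max())
    if peaks.size == 0:
        peaks = np.array([int(np.argmax(dens))])
    best = grid[peaks[np.argmin(np.abs(grid[peaks] - 0.5))]]
    return float(np.clip(2 * best, np.finfo(float).tiny, 1.0))


def compute_msf(obs: MutationObservation, tcf: float) -> float:
    """Mean sample fraction of a mutation given sample purity."""
    if not 0.0 < tcf <= 1.0:
        raise ValueError(f"TCF {tcf} outside (0, 1]")
    if obs.multiplicity_m < 1:
        raise ValueError("multiplicity M must be >= 1")
    total_cn = obs.cn_mutant + obs.cn_wildtype
    return obs.vaf * (total_cn * tcf + 2.0 * (1.0 - tcf)) / obs.multiplicity_m


def compute_mcf(msf: float, tcf: float, clip_warn: float = 5.0) -> float:
    """Mutated clone fraction in percent: 100 * MSF / TCF.

    Measurement noise can push the raw value past 100%; it is clipped
    into [0, 100], with a warning when clipping exceeds ``clip_warn``
    percentage points.
    """
    if tcf == 0:
        raise ValueError("TCF must be nonzero")
    raw = 100.0 * msf / tcf
    clipped = float(np.clip(raw, 0.0, 100.0))
    if abs(raw - clipped) > clip_warn:
        _warnings.warn(
            f"MCF {raw:.1f}% clipped to {clipped:.1f}% "
            f"(> {clip_warn} points); check VAF/CN/TCF inputs",
            stacklevel=2,
        )
    return clipped


def mcf_from_observation(obs: MutationObservation, tcf: float) -> float:
    """Convenience: MSF then MCF in one step."""
    return compute_mcf(compute_msf(obs, tcf), tcf)


def qc_filter(
    observations: dict[str, list[MutationObservation]],
    min_depth: int = 10,
    min_coverage: int = 200,
    require_diploid: bool = True,
) -> dict[str, list[MutationObservation]]:
    """Keep mutations passing depth/coverage/ploidy criteria in all samples.

    ``observations`` maps mutation id -> per-sample observations.  A
    mutation is kept only if, in every sample where it is observed,
    read depth >= ``min_depth``, total coverage >= ``min_coverage``,
    and (if ``require_diploid``) the locus lies in a diploid segment.
    """
    kept: dict[str, list[MutationObservation]] = {}
    for mut_id, obs_list in observations.items():
        ok = True
        for obs in obs_list:
            if obs.read_depth is not None and obs.read_depth < min_depth:
                ok = False
            if obs.total_coverage is not None and obs.total_coverage < min_coverage:
                ok = False
            if require_diploid and not obs.diploid:
                ok = False
        if ok:
            kept[mut_id] = obs_list
    return kept
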