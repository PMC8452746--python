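"""Genome model: chromosome lengths and centromere boundaries.

A small table of chromosome sizes is all the package needs: the event
unifier uses it to validate coordinates, the scope classifier to decide
whether a copy-number segment covers a whole chromosome or a chromosome
arm, and the simulator to draw random copy-number aberrations within
chromosome bounds.  A GRCh38 table is bundled; any tab-separated file
with columns ``chrom, length, centromere_start, centromere_end`` can be
supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = ["Chromosome", "GenomeModel", "load_genome"]


def _normalize_chrom(name: str) -> str:
    """Strip an optional ``chr`` prefix; chromosome names are case-preserving."""
    name = str(name).strip()
    if name.lower().startswith("chr"):
        name = name[3:]
    return name


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    centromere_start: int
    centromere_end: int

    @property
    def p_arm(self) -> tuple[int, int]:
        """1-based closed interval of the short arm."""
        return (1, self.centromere_start)

    @property
    def q_arm(self) -> tuple[int, int]:
        return (self.centromere_end, self.length)


class GenomeModel:
    """Lookup table of chromosomes keyed by normalized name."""

    def __init__(self, chromosomes: list[Chromosome]):
        self._chroms: dict[str, Chromosome] = {c.name: c for c in chromosomes}
        if not self._chroms:
            raise ValueError("genome model must contain at least one chromosome")

    def __contains__(self, chrom: str) -> bool:
        return _normalize_chrom(chrom) in self._chroms

    def __getitem__(self, chrom: str) -> Chromosome:
        key = _normalize_chrom(chrom)
        if key not in self._chroms:
            raise KeyError(f"unknown chromosome {chrom!r}")
        return self._chroms[key]

    def __iter__(self):
        return iter(self._chroms.values())

    def __len__(self) -> int:
        return len(self._chroms)

    @property
    def names(self) -> list[str]:
        return list(self._chroms)

    def normalize(self, chrom: str) -> str:
        key = _normalize_chrom(chrom)
        if key not in self._chroms:
            raise KeyError(f"unknown chromosome {chrom!r}")
        return key


def load_genome(path: str | Path | None = None) -> GenomeModel:
    """Load a genome model from a TSV, defaulting to the bundled GRCh38 table."""
    if path is None:
        ref = resources.files("clonedeconv").joinpath("data/genome_grch38.tsv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    required = {"chrom", "length", "centromere_start", "centromere_end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"genome table missing columns: {sorted(missing)}")
    chroms = [
        Chromosome(
            name=_normalize_chrom(r.chrom),
            length=int(r.length),
            centromere_start=int(r.centromere_start),
            centromere_end=int(r.centromere_end),
        )
        for r in df.itertuples()
    ]
    return GenomeModel(chroms)
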