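"""Developmental-stage signature scoring of DEG lists.

The seven stage gene sets (YS, E1, E2, P1, P2, A1, A2) span the microglial
developmental trajectory from yolk-sac progenitors through embryonic and
postnatal stages to adulthood. A DEG list is scored by the fraction of its
genes falling in each stage set (sets are a partition, so a gene counts
once); two lists are compared by standard two-set Venn counts; a generic
hypergeometric upper-tail test covers enrichment questions.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom

from .io import read_gmt, write_gmt

REQUIRED_STAGES = ("YS", "E1", "E2", "P1", "P2", "A1", "A2")


@dataclass
class StageSets:
    """Ordered, pairwise-disjoint developmental gene sets."""

    sets: dict[str, frozenset]

    def __post_init__(self) -> None:
        missing = [s for s in REQUIRED_STAGES if s not in self.sets]
        if missing:
            raise ValueError(f"missing stage sets: {missing}")

    @classmethod
    def from_lists(cls, sets: dict[str, list[str]], strict: bool = True) -> "StageSets":
        lowered = {
            name: frozenset(g.lower() for g in genes) for name, genes in sets.items()
        }
        missing = [s for s in REQUIRED_STAGES if s not in lowered]
        if missing:
            raise ValueError(f"missing stage sets: {missing}")
        if strict:
            seen: dict[str, str] = {}
            collisions = []
            for name in REQUIRED_STAGES:
                for g in sorted(lowered.get(name, ())):
                    if g in seen:
                        collisions.append((g, seen[g], name))
                    seen[g] = name
            if collisions:
                detail = ", ".join(f"{g!r} in {a} and {b}" for g, a, b in collisions[:10])
                raise ValueError(f"stage sets are not disjoint: {detail}")
        return cls(sets={name: lowered[name] for name in REQUIRED_STAGES})

    def names(self) -> tuple[str, ...]:
        return REQUIRED_STAGES


@dataclass
class OverlapProfile:
    per_stage: dict[str, tuple[int, float]]  # stage -> (n_overlap, pct_of_degs)
    n_unassigned: int
    pct_unassigned: float
    n_degs_total: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (stage, n, pct) for stage, (n, pct) in self.per_stage.items()
        ] + [("unassigned", self.n_unassigned, self.pct_unassigned)]
        return pd.DataFrame(rows, columns=["stage", "n_overlap", "pct_of_degs"])

    def to_dict(self) -> dict:
        return {
            "per_stage": {k: {"n": n, "pct": pct} for k, (n, pct) in self.per_stage.items()},
            "unassigned": {"n": self.n_unassigned, "pct": self.pct_unassigned},
            "n_degs_total": self.n_degs_total,
        }


def load_stage_sets(path, strict: bool = True) -> StageSets:
    """Load the seven stage sets from a GMT file, validating disjointness."""
    return StageSets.from_lists(read_gmt(path), strict=strict)


def save_stage_sets(sets: StageSets, path) -> None:
    write_gmt({k: sorted(v) for k, v in sets.sets.items()}, path)


def overlap_fractions(degs: list[str], sets: StageSets) -> OverlapProfile:
    """Fraction of a DEG list falling in each stage set (percent, 2 dp)."""
    if not degs:
        raise ValueError("DEG list is empty; fractions undefined")
    lowered = [g.lower() for g in degs]
    if len(set(lowered)) != len(lowered):
        raise ValueError("DEG list contains duplicates")
    total = len(lowered)
    per_stage = {}
    assigned = 0
    deg_set = set(lowered)
    for stage in sets.names():
        n = len(deg_set & sets.sets[stage])
        assigned += n
        per_stage[stage] = (n, round(100.0 * n / total, 2))
    n_un = total - assigned
    return OverlapProfile(
        per_stage=per_stage,
        n_unassigned=n_un,
        pct_unassigned=round(100.0 * n_un / total, 2),
        n_degs_total=total,
    )


def venn_compare(list_a: list[str], list_b: list[str]) -> tuple[int, int, int]:
    """(n_common, n_a_only, n_b_only) for two deduplicated gene lists."""
    a = {g.lower() for g in list_a}
    b = {g.lower() for g in list_b}
    return len(a & b), len(a - b), len(b - a)


def hypergeom_enrich(degs: list[str], gene_set: list[str], universe_size: int) -> float:
    """Upper-tail hypergeometric p for the observed DEG/set overlap."""
    d = {g.lower() for g in degs}
    s = {g.lower() for g in gene_set}
    k = len(d & s)
    if len(d) > universe_size or len(s) > universe_size:
        raise ValueError("set sizes exceed the universe")
    return float(hypergeom.sf(k - 1, universe_size, len(s), len(d)))
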