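"""Mendelian segregation tests for spore phenotype data.

A recessive nuclear mutation in a haploid x haploid yeast cross should
segregate 2:2 within complete tetrads and ~1:1 in bulk random-spore
counts. This module flags per-tetrad conformity, runs the exact two-sided
binomial test on spore counts, and simulates crosses under monogenic and
two-gene-independent null models for power checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

PHENOTYPES = ("resistant", "sensitive")


class GeneticsError(ValueError):
    """Malformed segregation input."""


@dataclass(frozen=True)
class TetradRecord:
    """Phenotypes of the four spores of one dissected tetrad."""

    tetrad_id: str
    spores: tuple[str, str, str, str]

    def __post_init__(self) -> None:
        if len(self.spores) != 4:
            raise GeneticsError(f"{self.tetrad_id}: a tetrad has exactly 4 spores")
        bad = set(self.spores) - set(PHENOTYPES)
        if bad:
            raise GeneticsError(f"{self.tetrad_id}: unknown phenotypes {sorted(bad)}")

    @property
    def n_resistant(self) -> int:
        return sum(1 for s in self.spores if s == "resistant")

    @property
    def is_two_two(self) -> bool:
        return self.n_resistant == 2


@dataclass(frozen=True)
class SporeCounts:
    """Bulk random-spore phenotype counts."""

    n_total: int
    n_resistant: int
    n_sensitive: int

    def __post_init__(self) -> None:
        if self.n_resistant + self.n_sensitive != self.n_total:
            raise GeneticsError("n_resistant + n_sensitive must equal n_total")
        if self.n_total < 1:
            raise GeneticsError("need at least one spore")


@dataclass
class TetradReport:
    n_tetrads: int
    n_conforming: int
    conforming_fraction: float
    nonconforming_ids: list[str]
    p_all_conforming_monogenic: float
    p_all_conforming_two_gene: float


def tetrad_pattern_test(
    tetrads: Sequence[TetradRecord],
    n_sim: int = 20000,
    seed: int = 0,
) -> TetradReport:
    """Check each tetrad for the 2:2 monogenic pattern.

    Under a monogenic model every complete tetrad is 2:2, so the
    probability of observing all tetrads conforming is 1. Under a
    two-gene-independent model (resistance requiring both mutant alleles)
    the per-tetrad conformity probability is estimated by simulation and
    raised to the number of tetrads.
    """
    if not tetrads:
        raise GeneticsError("no tetrads supplied")
    non = [t.tetrad_id for t in tetrads if not t.is_two_two]
    n = len(tetrads)
    n_conf = n - len(non)

    rng = np.random.default_rng(seed)
    sim = simulate_tetrads(n_sim, model="two-gene-independent", rng=rng)
    p_conf_two_gene = float(np.mean([t.is_two_two for t in sim]))
    return TetradReport(
        n_tetrads=n,
        n_conforming=n_conf,
        conforming_fraction=n_conf / n,
        nonconforming_ids=non,
        p_all_conforming_monogenic=1.0,
        p_all_conforming_two_gene=p_conf_two_gene ** n,
    )


def segregation_binomial_test(c: SporeCounts, p0: float = 0.5) -> float:
    """Exact two-sided binomial p-value for the resistant fraction.

    Two-sided by summation of all outcome probabilities no larger than the
    observed outcome's probability (the standard exact method).
    """
    return float(
        stats.binomtest(c.n_resistant, c.n_total, p0, alternative="two-sided").pvalue
    )


def counts_from_percent(n_total: int, percent_resistant: float) -> list[SporeCounts]:
    """Reconstruct integer spore counts from a printed percentage.

    Returns both rounding candidates when the percentage does not land on
    an integer count; a single record when it does.
    """
    exact = n_total * percent_resistant / 100.0
    lo, hi = int(np.floor(exact)), int(np.ceil(exact))
    candidates = sorted({lo, hi} & set(range(0, n_total + 1)))
    return [SporeCounts(n_total, k, n_total - k) for k in candidates]


def _tetrad_from_resistant_flags(tid: str, flags: Iterable[bool]) -> TetradRecord:
    return TetradRecord(
        tid, tuple("resistant" if f else "sensitive" for f in flags)  # type: ignore[arg-type]
    )


def simulate_tetrads(
    n_tetrads: int, model: str, rng: np.random.Generator
) -> list[TetradRecord]:
    """Draw tetrads under a segregation model.

    monogenic: every tetrad is 2 resistant : 2 sensitive (order shuffled).
    two-gene-independent: two unlinked loci segregate 2:2 independently;
    a spore is resistant only with mutant alleles at both.
    """
    out = []
    for i in range(n_tetrads):
        if model == "monogenic":
            flags = np.array([True, True, False, False])
            rng.shuffle(flags)
        elif model == "two-gene-independent":
            a = np.array([True, True, False, False])
            b = np.array([True, True, False, False])
            rng.shuffle(a)
            rng.shuffle(b)
            flags = a & b
        else:
            raise GeneticsError(f"unknown model {model!r}")
        out.append(_tetrad_from_resistant_flags(f"T{i + 1}", flags))
    return out


def simulate_cross(
    n_spores: int = 0,
    n_tetrads: int = 0,
    model: str = "monogenic",
    seed: int = 0,
) -> tuple[SporeCounts | None, list[TetradRecord]]:
    """Reproducible in-silico cross: bulk random spores and/or tetrads.

    Random spores under the monogenic model are Binomial(n, 0.5)
    resistant; under the two-gene model Binomial(n, 0.25).
    """
    if model not in {"monogenic", "two-gene-independent"}:
        raise GeneticsError(f"unknown model {model!r}")
    rng = np.random.default_rng(seed)
    counts = None
    if n_spores > 0:
        p = 0.5 if model == "monogenic" else 0.25
        k = int(rng.binomial(n_spores, p))
        counts = SporeCounts(n_spores, k, n_spores - k)
    tetrads = simulate_tetrads(n_tetrads, model, rng) if n_tetrads > 0 else []
    return counts, tetrads


def read_tetrads_tsv(path: str) -> list[TetradRecord]:
    """TSV with columns tetrad_id, s1..s4."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["tetrad_id", "s1", "s2", "s3", "s4"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise GeneticsError(f"{path}: missing columns {missing}")
    return [
        TetradRecord(row["tetrad_id"], (row["s1"], row["s2"], row["s3"], row["s4"]))
        for _, row in df.iterrows()
    ]
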