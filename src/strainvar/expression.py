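"""Differential-expression thresholding and gene-list arithmetic.

The stage consumes an already probe-summarized expression matrix (probes x
samples of positive intensities, two condition labels with replicates) and
applies the dual retention rule: two-sided t-test p-value strictly below
alpha AND linear fold change strictly above the ratio cutoff (or below its
reciprocal for down-regulation). No multiple-testing correction is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


class ExpressionError(ValueError):
    """Invalid expression matrix or design."""


@dataclass
class ExpressionMatrix:
    """Positive intensities: probes (rows) x samples (columns), with a
    condition label ('treated' or 'control') per sample column."""

    values: pd.DataFrame
    conditions: Mapping[str, str]  # column -> {"treated", "control"}

    def __post_init__(self) -> None:
        if self.values.index.hasnans or not self.values.index.is_unique:
            raise ExpressionError("probe ids must be unique and non-missing")
        unknown = set(self.conditions.values()) - {"treated", "control"}
        if unknown:
            raise ExpressionError(f"unknown condition labels: {sorted(unknown)}")
        missing = set(self.values.columns) - set(self.conditions)
        if missing:
            raise ExpressionError(f"columns without condition label: {sorted(missing)}")
        if (self.values <= 0).any().any():
            raise ExpressionError("intensities must be positive")

    def columns_for(self, condition: str) -> list[str]:
        return [c for c in self.values.columns if self.conditions[c] == condition]


@dataclass(frozen=True)
class DEResult:
    probe_id: str
    ratio: float          # linear fold change, treated/control of means
    p_value: float        # two-sided t-test on log2 intensities by default
    direction: str        # "up" or "down"
    retained: bool


def de_filter(
    m: ExpressionMatrix,
    alpha: float = 0.01,
    ratio: float = 2.0,
    equal_var: bool = False,
    log_scale: bool = True,
) -> list[DEResult]:
    """Apply the dual retention thresholds to every probe.

    Retained iff p < alpha (strict) and fold change > ratio for up or
    < 1/ratio for down (strict). The t-test is Welch two-sided on log2
    intensities by default; ``equal_var=True`` selects the pooled-variance
    test and ``log_scale=False`` tests linear intensities.
    """
    treated_cols = m.columns_for("treated")
    control_cols = m.columns_for("control")
    if len(treated_cols) < 2 or len(control_cols) < 2:
        raise ExpressionError(
            f"need >=2 replicates per condition, got {len(treated_cols)} treated "
            f"and {len(control_cols)} control"
        )
    treated = m.values[treated_cols].to_numpy(dtype=float)
    control = m.values[control_cols].to_numpy(dtype=float)
    ratios = treated.mean(axis=1) / control.mean(axis=1)
    t_in = np.log2(treated) if log_scale else treated
    c_in = np.log2(control) if log_scale else control
    pvals = stats.ttest_ind(t_in, c_in, axis=1, equal_var=equal_var).pvalue

    results = []
    for probe, r, p in zip(m.values.index, ratios, pvals):
        direction = "up" if r >= 1.0 else "down"
        fold_ok = r > ratio if direction == "up" else r < 1.0 / ratio
        retained = bool(p < alpha and fold_ok)
        results.append(DEResult(str(probe), float(r), float(p), direction, retained))
    return results


def set_overlap(
    results: Iterable[DEResult],
    gene_set: set[str],
    probe_to_gene: Mapping[str, str] | None = None,
) -> tuple[int, int]:
    """(n_up, n_down) among retained results whose gene is in ``gene_set``.

    ``probe_to_gene`` harmonizes id namespaces; unmapped probes are logged
    and excluded. With no map, probe ids are used as gene ids directly.
    """
    n_up = n_down = 0
    unmapped = 0
    for r in results:
        if not r.retained:
            continue
        if probe_to_gene is None:
            gene = r.probe_id
        elif r.probe_id in probe_to_gene:
            gene = probe_to_gene[r.probe_id]
        else:
            unmapped += 1
            continue
        if gene in gene_set:
            if r.direction == "up":
                n_up += 1
            else:
                n_down += 1
    if unmapped:
        logger.warning("%d retained probe(s) had no gene mapping, excluded", unmapped)
    return n_up, n_down


def transcriptome_fraction(n_de: int, n_probesets: int) -> float:
    """Percentage of the transcriptome called differentially expressed,
    rounded half-up to 2 decimals (so 372 of 5,841 probe sets -> 6.37)."""
    if n_probesets <= 0:
        raise ExpressionError("n_probesets must be positive")
    pct = Decimal(100 * n_de) / Decimal(n_probesets)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def read_expression_matrix(
    path: str,
    conditions: Mapping[str, str] | None = None,
    sep: str = "\t",
) -> ExpressionMatrix:
    """Read a delimited probes-x-samples table. If ``conditions`` is not
    given, column names must start with 'treated' or 'control'."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    if conditions is None:
        conditions = {}
        for c in df.columns:
            low = str(c).lower()
            if low.startswith("treated"):
                conditions[c] = "treated"
            elif low.startswith("control"):
                conditions[c] = "control"
            else:
                raise ExpressionError(
                    f"cannot infer condition for column {c!r}; pass labels explicitly"
                )
    return ExpressionMatrix(values=df, conditions=conditions)


def read_gene_set(path: str, name: str | None = None) -> set[str]:
    """One gene id per line; blank lines and '#' comments ignored."""
    members = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                members.add(line)
    return members
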