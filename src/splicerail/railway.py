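"""Probe-level "railway" statistics along a gene.

A railway plot carries the Manhattan-plot idea into transcriptomics: for
every probe of a gene, the log2 intensity is regressed on the cohort's CTG
repeat length (MAL); the y-axis shows the signed score
``sign(slope) * (-log10 p)`` of the two-sided no-association test, so
negative scores indicate splice-out events (intensity falling with repeat
length) and positive scores splice-in events.  Probes are ordered by
genomic position and coloured by probeset; horizontal thresholds mark the
nominal 0.05 level and the Bonferroni level 0.05/n (n = probes in the
plot), one pair per sign direction.

Fisher's method and a Bonferroni correction are provided for combining a
probeset-level p-value with an external discovery study's.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: Signed scores for exact (zero-residual) fits, where p underflows to 0.
SCORE_CAP = 300.0


@dataclass(frozen=True)
class ThresholdPair:
    """Nominal and multiplicity-corrected significance levels (p scale)."""

    nominal: float
    corrected: float

    @property
    def nominal_score(self) -> float:
        return -np.log10(self.nominal)

    @property
    def corrected_score(self) -> float:
        return -np.log10(self.corrected)


def probe_regression(intensities: np.ndarray, mal: np.ndarray) -> tuple[float, float]:
    """OLS slope of log2 intensity on MAL and its two-sided p-value.

    The p-value comes from the t statistic of the slope with n - 2 degrees
    of freedom.  Degenerate conventions: constant intensities give
    (0.0, 1.0); an exact non-constant linear fit gives p = 0.0 (the score is
    capped downstream); constant MAL is an error.
    """
    x = np.asarray(mal, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("MAL is constant; regression slope undefined")
    if np.ptp(y) == 0:
        return 0.0, 1.0
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = xc @ xc
    slope = (xc @ yc) / sxx
    resid = yc - slope * xc
    sse = resid @ resid
    dof = x.size - 2
    if sse <= np.finfo(float).eps * (yc @ yc):
        return float(slope), 0.0
    se = np.sqrt(sse / dof / sxx)
    t = slope / se
    p = 2.0 * stats.t.sf(abs(t), dof)
    return float(slope), float(min(p, 1.0))


def signed_score(slope: float, p_value: float, cap: float = SCORE_CAP) -> float:
    """``sign(slope) * (-log10 p)``; 0 when p = 1; capped when p = 0."""
    if not 0.0 <= p_value <= 1.0:
        raise ValueError(f"p-value {p_value} outside [0, 1]")
    if p_value == 0.0:
        magnitude = cap
    else:
        magnitude = min(-np.log10(p_value), cap)
    return float(np.sign(slope) * magnitude)


def railway_table(gene_table: pd.DataFrame, mal: pd.Series,
                  score_cap: float = SCORE_CAP) -> tuple[pd.DataFrame, ThresholdPair]:
    """Per-probe railway rows for one gene plus the threshold pair.

    ``gene_table`` is a ProbeTable slice (annotation + participant
    columns); ``mal`` is indexed by participant id.  Rows are ordered by
    ``genecode_left`` (ties broken by probe id) and keep the probeset id as
    the colouring key.  Thresholds use n = number of probes in this plot.
    """
    from .preprocess import participant_columns

    if len(gene_table) == 0:
        raise ValueError("gene table has no probes")
    cols = [c for c in participant_columns(gene_table) if c in mal.index]
    mal = mal.loc[cols].dropna()
    cols = list(mal.index)
    if not cols:
        raise ValueError("no participants shared between gene table and cohort")

    y = mal.to_numpy(dtype=float)
    rows = []
    for probe_id, row in gene_table.iterrows():
        slope, p = probe_regression(row[cols].to_numpy(dtype=float), y)
        rows.append(
            {
                "probe_id": str(probe_id),
                "probeset_id": row["probeset_id"],
                "position": int(row["genecode_left"]),
                "slope": slope,
                "p_value": p,
                "signed_score": signed_score(slope, p, cap=score_cap),
            }
        )
    frame = pd.DataFrame(rows).sort_values(
        ["position", "probe_id"], kind="mergesort", ignore_index=True
    )
    n = len(frame)
    thresholds = ThresholdPair(nominal=0.05, corrected=0.05 / n)
    return frame, thresholds


def fisher_combine(p_values) -> float:
    """Fisher's method: refer ``-2 * sum(ln p)`` to chi-square with 2k df."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    x = -2.0 * np.sum(np.log(p))
    return float(stats.chi2.sf(x, 2 * p.size))


def bonferroni(p: float, m: int) -> float:
    """Bonferroni correction: ``min(1, m * p)``."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if m < 1:
        raise ValueError("multiplicity factor must be >= 1")
    return float(min(1.0, m * p))


def railway_plot(frame: pd.DataFrame, thresholds: ThresholdPair, ax=None,
                 title: str | None = None):
    """Render a railway plot from :func:`railway_table` output.

    Probes of one probeset share a colour; faded lines mark the nominal
    0.05 thresholds and saturated lines the Bonferroni-corrected ones,
    symmetric about zero.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    probesets = list(dict.fromkeys(frame["probeset_id"]))
    cmap = plt.get_cmap("tab10")
    for i, ps in enumerate(probesets):
        sub = frame[frame["probeset_id"] == ps]
        ax.scatter(sub["position"], sub["signed_score"],
                   color=cmap(i % 10), label=str(ps), s=24)
    for level, alpha_ in ((thresholds.nominal_score, 0.3),
                          (thresholds.corrected_score, 0.9)):
        ax.axhline(level, color="blue", alpha=alpha_, lw=1)
        ax.axhline(-level, color="red", alpha=alpha_, lw=1)
    ax.axhline(0, color="grey", lw=0.5)
    ax.set_xlabel("genomic position (1-based)")
    ax.set_ylabel("signed -log10 p")
    if title:
        ax.set_title(title)
    return ax
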