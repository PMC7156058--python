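"""Normalisation, annotation filtering and per-gene probe tables.

The unit every downstream statistic consumes is the ProbeTable: per-probe
annotation (gene, probeset, 25-mer plus-strand sequence, 1-based inclusive
genomic coordinates, chip x/y) joined to quantile-normalised, log2
intensities, one column per participant.

Normalisation order follows the pipeline convention: quantile-normalise the
raw fluorescence intensities across participants, then log2-transform.
Coordinates are 1-based and both-ends inclusive throughout; half-open inputs
must be converted at the boundary by the caller.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cel import read_cel_v4, intensities_from_cel
from .synthetic import ANNOTATION_COLUMNS

logger = logging.getLogger(__name__)

#: Annotation filter: the strict protein-coding rule set.
DEFAULT_FILTER_RULES = {
    "transcript_type": {"protein_coding"},
    "gene_type": {"protein_coding"},
    "exon_type": {"CDS", "UTR"},
}


class ValidationError(ValueError):
    """Raised for non-positive/non-finite intensities or malformed tables."""


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalise columns (participants) of an intensity matrix.

    Every column is mapped onto the common reference distribution obtained
    by averaging the sorted columns, so afterwards the sorted intensity
    vectors of all participants are identical.  Ties within a column all
    receive the mean of the reference quantiles they span (average-ties
    rule).  Row and column labels are preserved.
    """
    values = matrix.to_numpy(dtype=float)
    if values.size == 0:
        raise ValidationError("empty intensity matrix")
    if not np.all(np.isfinite(values)):
        raise ValidationError("intensity matrix contains non-finite values")
    if np.any(values <= 0):
        raise ValidationError("intensity matrix contains non-positive values")

    n, _ = values.shape
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty(n, dtype=float)
        assigned[order] = reference
        # average-ties: every member of a tied run receives the mean of the
        # reference quantiles the run spans
        _, inverse, counts = np.unique(col, return_inverse=True, return_counts=True)
        sums = np.bincount(inverse, weights=assigned)
        out[:, j] = sums[inverse] / counts[inverse]
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def log2_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log2; rejects non-positive values."""
    values = matrix.to_numpy(dtype=float)
    if np.any(~np.isfinite(values)) or np.any(values <= 0):
        raise ValidationError("log2 transform requires finite, positive values")
    return pd.DataFrame(np.log2(values), index=matrix.index, columns=matrix.columns)


@dataclass
class FilterReport:
    """Retention bookkeeping for :func:`filter_probes`."""

    n_input: int
    n_retained: int
    excluded_by_rule: dict
    n_missing_annotation: int

    def to_frame(self) -> pd.DataFrame:
        rows = [("input", self.n_input), ("retained", self.n_retained)]
        rows += [(f"excluded_{k}", v) for k, v in self.excluded_by_rule.items()]
        rows.append(("excluded_missing_annotation", self.n_missing_annotation))
        return pd.DataFrame(rows, columns=["category", "count"])


def filter_probes(
    annotation: pd.DataFrame,
    rules: dict | None = None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Retain probes whose target passes every annotation rule.

    The default rules keep probes on protein-coding transcripts of
    protein-coding genes covering CDS or UTR exons.  A probe with a missing
    annotation field is excluded and counted, never fatal.  Probe order is
    preserved, so permuting the input permutes the output identically.
    """
    rules = DEFAULT_FILTER_RULES if rules is None else rules
    missing_cols = [c for c in rules if c not in annotation.columns]
    if missing_cols:
        raise ValidationError(f"annotation lacks filter columns: {missing_cols}")

    keep = np.ones(len(annotation), dtype=bool)
    missing = np.zeros(len(annotation), dtype=bool)
    excluded_by_rule: dict[str, int] = {}
    for column, allowed in rules.items():
        col = annotation[column]
        is_missing = col.isna() | (col.astype(str).str.len() == 0)
        passes = col.isin(list(allowed)) & ~is_missing
        excluded_by_rule[column] = int((keep & ~passes & ~is_missing).sum())
        missing |= (keep & is_missing).to_numpy()
        keep &= passes.to_numpy()
    report = FilterReport(
        n_input=len(annotation),
        n_retained=int(keep.sum()),
        excluded_by_rule=excluded_by_rule,
        n_missing_annotation=int(missing.sum()),
    )
    return annotation.loc[keep].copy(), report


def build_probe_table(
    raw: pd.DataFrame,
    annotation: pd.DataFrame,
    rules: dict | None = None,
    normalize: bool = True,
) -> tuple[pd.DataFrame, FilterReport]:
    """Filter, quantile-normalise and log2-transform into a ProbeTable.

    Returns annotation columns followed by one log2-intensity column per
    participant, indexed by probe id.
    """
    filtered, report = filter_probes(annotation, rules)
    intensities = raw.loc[filtered.index]
    if normalize:
        intensities = log2_transform(quantile_normalize(intensities))
    table = pd.concat([filtered[ANNOTATION_COLUMNS], intensities], axis=1)
    return table, report


def load_cel_directory(
    cel_paths,
    annotation: pd.DataFrame,
) -> pd.DataFrame:
    """Assemble a raw probes x participants matrix from CEL v4 files.

    Participant ids are the CEL file stems; probe intensities are looked up
    at each probe's chip (x, y) from the annotation.
    """
    xs = annotation["x"].to_numpy()
    ys = annotation["y"].to_numpy()
    columns = {}
    for path in sorted(Path(p) for p in cel_paths):
        cel = read_cel_v4(str(path))
        columns[path.stem] = intensities_from_cel(cel, xs, ys)
    if not columns:
        raise ValidationError("no CEL files supplied")
    return pd.DataFrame(columns, index=annotation.index, dtype=float)


def load_tabular_matrix(path) -> pd.DataFrame:
    """Plain-text fallback: tab-delimited probe-id rows, participant columns."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_annotation(path) -> pd.DataFrame:
    """Read a tab-delimited probe annotation table indexed by probe_id."""
    return pd.read_csv(path, sep="\t", index_col="probe_id")


def read_phenotype(path) -> pd.Series:
    """Read the participant_id / mal phenotype table as a MAL series."""
    frame = pd.read_csv(path, sep="\t")
    return pd.Series(
        frame["mal"].to_numpy(dtype=float),
        index=list(frame["participant_id"]),
        name="mal",
    )


def emit_gene_tables(table: pd.DataFrame, directory, on_duplicate: str = "error") -> list:
    """Write one tab-delimited file per gene in the exact table dialect.

    Header: the nine annotation columns, then one ``patient_*`` column per
    participant; one row per probe; sequences already reported 5'->3' on the
    plus strand.  Files are named ``<gene>.tsv``; a duplicate filename (two
    gene symbols colliding case-insensitively) raises unless
    ``on_duplicate='suffix'``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    seen: dict[str, str] = {}
    for gene, rows in table.groupby("gene_name", sort=True):
        stem = str(gene)
        key = stem.lower()
        if key in seen:
            if on_duplicate == "suffix":
                stem = f"{stem}_{sum(k.startswith(key) for k in seen) + 1}"
                logger.warning("duplicate gene filename %s, writing %s", gene, stem)
            else:
                raise ValidationError(
                    f"gene symbols {seen[key]!r} and {gene!r} collide as filenames"
                )
        seen[key] = str(gene)
        path = directory / f"{stem}.tsv"
        rows.to_csv(path, sep="\t", index=False)
        written.append(path)
    return written


def read_gene_table(path) -> pd.DataFrame:
    """Re-parse a per-gene table written by :func:`emit_gene_tables`."""
    return pd.read_csv(path, sep="\t")


def participant_columns(table: pd.DataFrame) -> list:
    """The intensity columns of a ProbeTable (everything past annotation)."""
    return [c for c in table.columns if c not in ANNOTATION_COLUMNS]


def pca_report(table: pd.DataFrame, n_components: int = 2) -> pd.DataFrame:
    """Participant scores on the top principal components of the log2 matrix.

    Offered as an outlier-screening report only: no sample is excluded
    automatically, since outlier rejection in this setting is a judgement
    call made by inspection.
    """
    from sklearn.decomposition import PCA

    cols = participant_columns(table)
    X = table[cols].to_numpy(dtype=float).T  # participants x probes
    k = min(n_components, *X.shape)
    scores = PCA(n_components=k).fit_transform(X - X.mean(axis=0))
    return pd.DataFrame(
        scores, index=cols, columns=[f"PC{i + 1}" for i in range(k)]
    )
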