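"""Synthetic cohorts and exon-array probe intensities.

Emulates the data a repeat-expansion splicing-biomarker study produces: a
small adult-onset cohort whose phenotype is the modal CTG-repeat allele
length (MAL, repeat units) measured in blood, and probe-level fluorescence
intensities from an exon chip on which every targeted region is covered by a
probeset of up to four 25-mer probes.

The generative model, per probe ``j`` and participant ``i``::

    log2 intensity[j, i] = baseline_j + beta_j * z(MAL_i) + eps,
    eps ~ N(0, noise_sd^2)

where ``z(MAL)`` is the cohort-standardised MAL, ``beta_j = 0`` for null
probes and ``beta_j = +/- effect_beta`` for the affected probes of biomarker
genes.  Raw (CEL-scale) intensities are ``2**log2``, so quantile
normalisation and the log2 transform downstream are genuinely exercised.
MAL is drawn log-uniformly over ``mal_range``, mimicking the right-skewed
distribution of an adult-onset cohort.

Within a biomarker gene, each probeset carries one effect direction (a
splice-in or splice-out event) and a configurable fraction of its probes is
left unaffected, so probesets mix signal and null probes the way real
exon-level events do.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cel import CelMatrix, default_header, write_cel_v4

_NUCLEOTIDES = np.array(list("ACGT"))
_REVCOMP = str.maketrans("ACGT", "TGCA")

#: Exact annotation column order shared with the per-gene table dialect.
ANNOTATION_COLUMNS = [
    "gene_name",
    "probeset_id",
    "seq5to3plus",
    "chrom",
    "strand",
    "genecode_left",
    "genecode_right",
    "x",
    "y",
]

#: Extra annotation columns consumed by the probe filter.
FILTER_COLUMNS = ["transcript_type", "gene_type", "exon_type"]


class ConfigurationError(ValueError):
    """Raised when a synthetic-data configuration violates its invariants."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the generator.

    Parameters
    ----------
    n_participants : int
        Cohort size; the default mirrors a complete-tissue collection of 27.
    n_genes, probesets_per_gene, probes_per_probeset : int
        Chip layout; at most 4 probes per probeset (chip constraint).
    frac_biomarker_genes : float
        Fraction of genes whose expression tracks MAL.
    effect_beta : float
        log2-intensity change per standardised MAL unit at affected probes.
    frac_unaffected_probes : float
        Fraction of probes inside biomarker genes left with no MAL effect.
    noise_sd, baseline_mean, baseline_sd : float
        log2-intensity units.
    mal_range : tuple
        (min, max) CTG repeat units; MAL is log-uniform over this range.
    n_missing_mal : int
        Participants whose MAL is withheld (at most 1, mimicking a single
        measurement refusal).
    """

    n_participants: int = 27
    n_genes: int = 50
    probesets_per_gene: int = 2
    probes_per_probeset: int = 4
    frac_biomarker_genes: float = 0.2
    effect_beta: float = 2.0
    frac_unaffected_probes: float = 0.5
    noise_sd: float = 0.5
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    mal_range: tuple[float, float] = (100.0, 1300.0)
    n_missing_mal: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        if self.n_genes < 1 or self.probesets_per_gene < 1:
            raise ConfigurationError("n_genes and probesets_per_gene must be >= 1")
        if not 1 <= self.probes_per_probeset <= 4:
            raise ConfigurationError(
                "probes_per_probeset must be in 1..4 (a probeset holds up to "
                "four probes)"
            )
        if not 0.0 <= self.frac_biomarker_genes <= 1.0:
            raise ConfigurationError("frac_biomarker_genes must be in [0, 1]")
        if not 0.0 <= self.frac_unaffected_probes <= 1.0:
            raise ConfigurationError("frac_unaffected_probes must be in [0, 1]")
        if self.noise_sd < 0 or self.baseline_sd < 0:
            raise ConfigurationError("noise_sd and baseline_sd must be >= 0")
        lo, hi = self.mal_range
        if not (0 < lo < hi):
            raise ConfigurationError("mal_range must satisfy 0 < min < max")
        if not 0 <= self.n_missing_mal <= 1:
            raise ConfigurationError("n_missing_mal must be 0 or 1")

    @property
    def n_probes(self) -> int:
        return self.n_genes * self.probesets_per_gene * self.probes_per_probeset


@dataclass
class SyntheticDataset:
    """Everything one generated study comprises."""

    config: SyntheticConfig
    cohort: pd.DataFrame  # participant_id, mal (NaN where withheld)
    raw_intensities: pd.DataFrame  # probes x participants, CEL scale
    annotation: pd.DataFrame  # per-probe, ANNOTATION_COLUMNS + FILTER_COLUMNS
    biomarker_genes: list[str]
    affected_probes: pd.Index
    probe_effects: pd.Series  # per-probe beta actually applied
    chip_shape: tuple[int, int] = (0, 0)  # (n_rows, n_cols)

    @property
    def participant_ids(self) -> list[str]:
        return list(self.cohort["participant_id"])


def generate_cohort(cfg: SyntheticConfig) -> pd.DataFrame:
    """Draw a cohort with log-uniform MAL over ``cfg.mal_range``.

    Returns a frame with ``participant_id`` and ``mal`` columns;
    ``cfg.n_missing_mal`` participants get a missing (NaN) MAL.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x101]))
    lo, hi = cfg.mal_range
    mal = np.exp(rng.uniform(math.log(lo), math.log(hi), size=cfg.n_participants))
    ids = [f"patient_{i + 1:03d}" for i in range(cfg.n_participants)]
    cohort = pd.DataFrame({"participant_id": ids, "mal": mal})
    if cfg.n_missing_mal:
        drop = rng.integers(0, cfg.n_participants, size=cfg.n_missing_mal)
        cohort.loc[drop, "mal"] = np.nan
    return cohort


def _random_sequences(rng: np.random.Generator, n: int, length: int = 25) -> np.ndarray:
    idx = rng.integers(0, 4, size=(n, length))
    return np.array(["".join(row) for row in _NUCLEOTIDES[idx]])


def reverse_complement(seq: str) -> str:
    return seq.translate(_REVCOMP)[::-1]


def generate_intensities(cfg: SyntheticConfig, cohort: pd.DataFrame) -> SyntheticDataset:
    """Generate raw probe intensities plus annotation for a cohort.

    The latent MAL of a participant whose phenotype is withheld still drives
    their expression (the biology does not know about the refusal); only the
    phenotype table hides it.
    """
    if len(cohort) != cfg.n_participants:
        raise ConfigurationError(
            f"cohort has {len(cohort)} participants, config expects "
            f"{cfg.n_participants}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x202]))

    n_probes = cfg.n_probes
    genes = [f"GENE{g + 1:04d}" for g in range(cfg.n_genes)]
    probes_per_gene = cfg.probesets_per_gene * cfg.probes_per_probeset

    gene_col = np.repeat(genes, probes_per_gene)
    probeset_index = np.tile(
        np.repeat(np.arange(cfg.probesets_per_gene), cfg.probes_per_probeset),
        cfg.n_genes,
    )
    probeset_col = np.array(
        [f"{g}_ps{s + 1}" for g, s in zip(gene_col, probeset_index)]
    )

    # Genomic layout: genes placed head to tail on one contig, probes tiled
    # left to right, 1-based inclusive coordinates, 25 bases each.
    gene_strand = rng.choice(["+", "-"], size=cfg.n_genes)
    strand_col = np.repeat(gene_strand, probes_per_gene)
    left = 1 + 1000 * np.repeat(np.arange(cfg.n_genes), probes_per_gene) + 30 * np.tile(
        np.arange(probes_per_gene), cfg.n_genes
    )
    right = left + 24

    design_seq = _random_sequences(rng, n_probes)
    seq5to3plus = np.array(
        [
            reverse_complement(s) if st == "-" else s
            for s, st in zip(design_seq, strand_col)
        ]
    )

    # Chip grid: probes fill the grid row-major; remaining cells are
    # background (filled at write time).
    n_cols = max(2, math.ceil(math.sqrt(n_probes)))
    n_rows = math.ceil(n_probes / n_cols)
    probe_idx = np.arange(n_probes)
    x = probe_idx % n_cols
    y = probe_idx // n_cols

    probe_ids = pd.Index(
        [f"{ps}_p{probe_idx[i] % cfg.probes_per_probeset + 1}" for i, ps in enumerate(probeset_col)],
        name="probe_id",
    )

    annotation = pd.DataFrame(
        {
            "gene_name": gene_col,
            "probeset_id": probeset_col,
            "seq5to3plus": seq5to3plus,
            "chrom": "chr1",
            "strand": strand_col,
            "genecode_left": left,
            "genecode_right": right,
            "x": x,
            "y": y,
            "transcript_type": "protein_coding",
            "gene_type": "protein_coding",
            "exon_type": "CDS",
            "design_sequence": design_seq,
        },
        index=probe_ids,
    )

    # Effects: biomarker genes drawn without replacement; each probeset gets
    # one direction; a fraction of probes stays unaffected.
    n_biomarker = round(cfg.frac_biomarker_genes * cfg.n_genes)
    biomarker_genes = sorted(
        rng.choice(genes, size=n_biomarker, replace=False).tolist()
    )
    probeset_sign = {
        ps: rng.choice([-1.0, 1.0])
        for ps in pd.unique(probeset_col)
    }
    beta = np.zeros(n_probes)
    in_biomarker = np.isin(gene_col, biomarker_genes)
    affected = in_biomarker & (rng.random(n_probes) >= cfg.frac_unaffected_probes)
    beta[affected] = cfg.effect_beta * np.array(
        [probeset_sign[ps] for ps in probeset_col[affected]]
    )

    mal = cohort["mal"].to_numpy(dtype=float)
    latent = mal.copy()
    if np.isnan(latent).any():
        lo, hi = cfg.mal_range
        latent[np.isnan(latent)] = np.exp(
            rng.uniform(math.log(lo), math.log(hi), size=int(np.isnan(latent).sum()))
        )
    z = (latent - latent.mean()) / (latent.std(ddof=0) or 1.0)

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=n_probes)
    log2_signal = (
        baseline[:, None]
        + beta[:, None] * z[None, :]
        + rng.normal(0.0, cfg.noise_sd, size=(n_probes, cfg.n_participants))
    )
    raw = pd.DataFrame(
        np.exp2(log2_signal),
        index=probe_ids,
        columns=list(cohort["participant_id"]),
    )

    return SyntheticDataset(
        config=cfg,
        cohort=cohort,
        raw_intensities=raw,
        annotation=annotation,
        biomarker_genes=biomarker_genes,
        affected_probes=probe_ids[affected],
        probe_effects=pd.Series(beta, index=probe_ids, name="beta"),
        chip_shape=(n_rows, n_cols),
    )


def generate_dataset(cfg: SyntheticConfig) -> SyntheticDataset:
    """Convenience: :func:`generate_cohort` + :func:`generate_intensities`."""
    return generate_intensities(cfg, generate_cohort(cfg))


def write_fixture(dataset: SyntheticDataset, directory) -> dict:
    """Write a study to disk: one CEL v4 file per participant, an annotation
    table and a phenotype table.

    Background cells (grid positions not holding a probe) receive the chip's
    baseline-scale constant 64.0 so files are dense like real scans.
    Returns a dict of the written paths.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    n_rows, n_cols = dataset.chip_shape
    ann = dataset.annotation

    cel_paths = []
    xs = ann["x"].to_numpy()
    ys = ann["y"].to_numpy()
    for pid in dataset.raw_intensities.columns:
        mean = np.full((n_rows, n_cols), 64.0, dtype=np.float32)
        mean[ys, xs] = dataset.raw_intensities[pid].to_numpy(dtype=np.float32)
        cel = CelMatrix(
            n_cols=n_cols,
            n_rows=n_rows,
            mean_intensity=mean,
            stdev=np.full((n_rows, n_cols), 1.0, dtype=np.float32),
            pixel_count=np.full((n_rows, n_cols), 9, dtype=np.int16),
            header_text=default_header(n_cols, n_rows),
        )
        path = directory / f"{pid}.CEL"
        path.write_bytes(write_cel_v4(cel))
        cel_paths.append(path)

    annotation_path = directory / "annotation.tsv"
    ann_out = ann[ANNOTATION_COLUMNS + FILTER_COLUMNS].copy()
    ann_out.insert(0, "probe_id", ann.index)
    ann_out.to_csv(annotation_path, sep="\t", index=False)

    phenotype_path = directory / "phenotype.tsv"
    dataset.cohort.to_csv(phenotype_path, sep="\t", index=False)

    gene_sets_path = directory / "biomarker_genes.txt"
    gene_sets_path.write_text("".join(f"{g}\n" for g in dataset.biomarker_genes))

    return {
        "cel": cel_paths,
        "annotation": annotation_path,
        "phenotype": phenotype_path,
        "biomarker_genes": gene_sets_path,
    }
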