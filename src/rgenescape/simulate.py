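"""Synthetic StudyDataset generator with planted, recoverable structure.

The generator emulates the statistical shape of a cross-lab TPM
meta-analysis: a log-normal abundance bulk, a small constitutively
expressed "core" of R-genes, a planted fraction of R-genes that are never
expressed, gene-specific BioProject (batch) and tissue effects, and
treatment-responsive genes with a planted log2 fold change.  The emitted
:class:`GroundTruth` records every planted set so downstream stages can be
scored for recovery.

Model
-----
Raw abundance of gene g in library l:

    a_gl = exp( mu_g + b_{g,B(l)} + t_{g,T(l)} + e_gl ) * 2^{s_g * fc * I[l treated]}

with gene baselines mu_g ~ Normal(m, sd) (R-genes shifted down by
``r_gene_log_shift`` — most R-genes sit near or below the detection
threshold, unlike the genomic bulk), gene-by-BioProject effects
b ~ Normal(0, bioproject_effect_sd), gene-by-tissue effects
t ~ Normal(0, tissue_effect_sd) and residual noise e ~ Normal(0, noise_sd),
all on the natural-log scale.  Planted off genes have a_gl = 0 everywhere;
planted core genes draw mu_g from a high-abundance component so their TPM
stays far above the on/off threshold in every library.  Columns are then
rescaled to TPM (sum 1e6), so batch effects are gene-specific relative
shifts — a uniform per-library scaling would cancel in TPM.

Treatment effects are applied before the TPM rescaling, so the
compositional distortion of non-responsive genes present in real TPM data
is present here too.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .datamodel import (
    NULL_ORGANISM,
    ExpressionMatrix,
    GeneAnnotation,
    LibraryMetadata,
    StudyDataset,
    validate_dataset,
)

__all__ = ["SimulationConfig", "GroundTruth", "simulate_dataset", "renormalize_to_tpm"]


@dataclass
class SimulationConfig:
    """Knobs for :func:`simulate_dataset`.

    Log-scale parameters are natural-log; ``treatment_effect_log2fc`` is in
    log2 units to match how fold changes are reported downstream.
    """

    n_genes: int = 4000
    n_r_genes: int = 400
    n_libraries: int = 100
    n_bioprojects: int = 8
    tissues: tuple[str, ...] = ("leaf", "root", "stem", "fruit")
    core_fraction: float = 0.0625      # of R-genes; 25/400 by default
    off_fraction: float = 0.20         # of R-genes never expressed
    baseline_log_mean: float = 0.0
    baseline_log_sd: float = 1.5
    r_gene_log_shift: float = -3.0     # R-gene bulk sits well below the genomic bulk
    core_log_mean: float = 5.7         # ~ exp(5.7) = 300 raw units, TPM >> 1
    core_log_sd: float = 0.5
    bioproject_effect_sd: float = 1.0
    tissue_effect_sd: float = 0.5
    noise_sd: float = 0.25
    treatment_effect_log2fc: float = 2.0
    de_up_fraction: float = 0.725      # share of planted responders that go up
    n_de_r_genes: int = 40
    replicates: int = 3                # per treatment arm within a stratum
    dpi_choices: tuple[int, ...] = (1, 2, 3, 5, 7)
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_genes, self.n_r_genes, self.n_libraries, self.n_bioprojects) <= 0:
            raise ValueError("all counts must be positive")
        if self.n_r_genes > self.n_genes:
            raise ValueError("n_r_genes cannot exceed n_genes")
        if not (0 <= self.core_fraction and 0 <= self.off_fraction):
            raise ValueError("fractions must be non-negative")
        if self.core_fraction + self.off_fraction > 1:
            raise ValueError("core_fraction + off_fraction must be <= 1")
        for name in ("baseline_log_sd", "bioproject_effect_sd", "tissue_effect_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        n_core = round(self.core_fraction * self.n_r_genes)
        n_off = round(self.off_fraction * self.n_r_genes)
        if n_core + n_off + self.n_de_r_genes > self.n_r_genes:
            raise ValueError(
                "core + off + DE gene counts exceed n_r_genes "
                f"({n_core} + {n_off} + {self.n_de_r_genes} > {self.n_r_genes})"
            )
        if self.replicates < 2:
            raise ValueError("replicates per arm must be >= 2")
        if not self.tissues:
            raise ValueError("at least one tissue required")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class GroundTruth:
    """Planted structure emitted alongside a simulated dataset."""

    core_gene_ids: list[str]
    off_gene_ids: list[str]
    de_effects: dict[str, float]          # gene id -> signed log2 fold change
    library_factors: pd.DataFrame         # copy of the metadata table

    @property
    def de_gene_ids(self) -> list[str]:
        return list(self.de_effects)

    def to_frame(self) -> pd.DataFrame:
        rows = [("core", g, 0.0) for g in self.core_gene_ids]
        rows += [("off", g, 0.0) for g in self.off_gene_ids]
        rows += [("de", g, fc) for g, fc in self.de_effects.items()]
        return pd.DataFrame(rows, columns=["role", "gene_id", "log2fc"])


def renormalize_to_tpm(raw: pd.DataFrame | ExpressionMatrix) -> ExpressionMatrix:
    """Scale every library column of a non-negative matrix to sum 1e6."""
    df = raw.data if isinstance(raw, ExpressionMatrix) else raw
    vals = df.to_numpy(dtype=float)
    if vals.size == 0:
        raise ValueError("cannot TPM-normalize an empty matrix")
    if (vals < 0).any():
        raise ValueError("raw abundances must be non-negative")
    sums = vals.sum(axis=0)
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        raise ValueError(
            "all-zero library column(s): " + ", ".join(str(df.columns[i]) for i in zero)
        )
    scaled = vals * (1e6 / sums)
    return ExpressionMatrix(pd.DataFrame(scaled, index=df.index, columns=df.columns))


def _build_metadata(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Assemble the library factor table.

    Libraries are split as evenly as possible across BioProjects.  Within a
    BioProject, libraries come in blocks of ``2 * replicates``: one mock arm
    and one pathogen arm sharing tissue and dpi, so the differential-
    expression pairing finds complete strata.  Leftover libraries fall into
    a final (possibly incomplete) block.
    """
    organisms = [
        ("P_infestans", "oomycete", "hemibiotroph"),
        ("B_cinerea", "fungus", "necrotroph"),
        ("R_solanacearum", "bacterium", "biotroph"),
        ("M_incognita", "nematode", "biotroph"),
        ("PVY", "virus", "biotroph"),
    ]
    counts = np.full(cfg.n_bioprojects, cfg.n_libraries // cfg.n_bioprojects)
    counts[: cfg.n_libraries % cfg.n_bioprojects] += 1
    rows = []
    lib_no = 0
    for b in range(cfg.n_bioprojects):
        bp = f"BP{b + 1:02d}"
        org = organisms[b % len(organisms)]
        cultivar = rng.choice(["susceptible", "resistant"])
        layout = rng.choice(["single", "paired"])
        block = 2 * cfg.replicates
        for i in range(counts[b]):
            unit = i // block
            within = i % block
            tissue = cfg.tissues[(b + unit) % len(cfg.tissues)]
            dpi = int(cfg.dpi_choices[(b * 3 + unit) % len(cfg.dpi_choices)])
            treated = within >= cfg.replicates
            rows.append(
                {
                    "library_id": f"LIB{lib_no + 1:04d}",
                    "bioproject": bp,
                    "tissue": tissue,
                    "treatment_class": "pathogen" if treated else "mock",
                    "organism": org[0] if treated else NULL_ORGANISM,
                    "organism_kingdom": org[1] if treated else NULL_ORGANISM,
                    "organism_lifecycle": org[2] if treated else NULL_ORGANISM,
                    "dpi": dpi,
                    "cultivar_status": str(cultivar),
                    "seq_layout": str(layout),
                    "depth_category": int(rng.integers(1, 6)),
                }
            )
            lib_no += 1
    return pd.DataFrame(rows)


def _build_annotation(cfg: SimulationConfig, gene_ids, rng: np.random.Generator) -> pd.DataFrame:
    """Place genes on chromosomes with exponential inter-gene gaps.

    A handful of R-genes (5%) get an unknown position, mirroring real
    repertoires where some genes lack verified coordinates.
    """
    n_chrom = 5
    chrom_of = rng.integers(0, n_chrom, size=cfg.n_genes)
    gaps = rng.exponential(scale=50_000, size=cfg.n_genes).astype(np.int64) + 500
    starts = np.zeros(cfg.n_genes, dtype=np.int64)
    for c in range(n_chrom):
        idx = np.flatnonzero(chrom_of == c)
        starts[idx] = np.cumsum(gaps[idx])
    lengths = rng.integers(1_000, 5_000, size=cfg.n_genes)
    is_r = np.zeros(cfg.n_genes, dtype=bool)
    is_r[: cfg.n_r_genes] = True
    unknown = np.zeros(cfg.n_genes, dtype=bool)
    n_unknown = int(0.05 * cfg.n_r_genes)
    if n_unknown:
        unknown[rng.choice(cfg.n_r_genes, size=n_unknown, replace=False)] = True
    full_length = is_r & (rng.random(cfg.n_genes) < 0.7)
    tbl = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chrom": [f"chr{c + 1:02d}" for c in chrom_of],
            "start": starts.astype(float),
            "end": (starts + lengths).astype(float),
            "is_r_gene": is_r,
            "is_full_length": full_length,
        }
    )
    tbl.loc[unknown, ["chrom", "start", "end"]] = [pd.NA, np.nan, np.nan]
    return tbl


def simulate_dataset(config: SimulationConfig) -> tuple[StudyDataset, GroundTruth]:
    """Draw a complete synthetic study with planted ground truth.

    Deterministic given ``config.seed``: the same config yields bitwise
    identical outputs.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    gene_ids = [f"RG{i + 1:04d}" for i in range(cfg.n_r_genes)] + [
        f"G{i + 1:05d}" for i in range(cfg.n_genes - cfg.n_r_genes)
    ]
    metadata = _build_metadata(cfg, rng)
    annotation = _build_annotation(cfg, gene_ids, rng)

    # planted roles among R-genes: core, off, DE, bulk (disjoint)
    n_core = round(cfg.core_fraction * cfg.n_r_genes)
    n_off = round(cfg.off_fraction * cfg.n_r_genes)
    order = rng.permutation(cfg.n_r_genes)
    core_idx = np.sort(order[:n_core])
    off_idx = np.sort(order[n_core : n_core + n_off])
    de_idx = np.sort(order[n_core + n_off : n_core + n_off + cfg.n_de_r_genes])

    # gene baselines (natural log of raw abundance)
    mu = rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=cfg.n_genes)
    mu[: cfg.n_r_genes] += cfg.r_gene_log_shift
    mu[core_idx] = rng.normal(cfg.core_log_mean, cfg.core_log_sd, size=n_core)

    bp_codes = pd.Categorical(metadata["bioproject"]).codes
    tis_codes = pd.Categorical(metadata["tissue"]).codes
    bp_eff = rng.normal(0.0, cfg.bioproject_effect_sd, size=(cfg.n_genes, bp_codes.max() + 1))
    tis_eff = rng.normal(0.0, cfg.tissue_effect_sd, size=(cfg.n_genes, tis_codes.max() + 1))
    noise = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, cfg.n_libraries))

    log_raw = mu[:, None] + bp_eff[:, bp_codes] + tis_eff[:, tis_codes] + noise
    raw = np.exp(log_raw)

    # planted treatment response, applied before TPM rescaling
    signs = np.where(rng.random(cfg.n_de_r_genes) < cfg.de_up_fraction, 1.0, -1.0)
    effects = signs * cfg.treatment_effect_log2fc
    treated = (metadata["treatment_class"] != "mock").to_numpy()
    if cfg.n_de_r_genes:
        raw[np.ix_(de_idx, np.flatnonzero(treated))] *= 2.0 ** effects[:, None]

    raw[off_idx, :] = 0.0

    matrix = renormalize_to_tpm(
        pd.DataFrame(raw, index=gene_ids, columns=metadata["library_id"].tolist())
    )
    dataset = validate_dataset(matrix, LibraryMetadata(metadata), GeneAnnotation(annotation))
    truth = GroundTruth(
        core_gene_ids=[gene_ids[i] for i in core_idx],
        off_gene_ids=[gene_ids[i] for i in off_idx],
        de_effects={gene_ids[i]: float(e) for i, e in zip(de_idx, effects)},
        library_factors=metadata.copy(),
    )
    return dataset, truth
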