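"""Synthetic expression and qPCR data with the study's sample structure.

The generators emulate the cohorts the analysis pipeline expects:

* a microarray cohort of 60 medullary thyroid cancer samples — 22 hereditary
  (16 MEN2A-like, 2 MEN2B-like, 4 with RET mutations outside exons 10/11/16)
  and 38 sporadic (5 MEN2A-like, 7 MEN2B-like, 7 other RET-mutant,
  15 RET-negative, 4 of unknown somatic status) — whose 21 + 9 MEN2A/MEN2B
  subset forms the mutation-contrast set;
* an independent qPCR validation cohort (16 MEN2A-like vs 9 MEN2B-like) with
  three reference genes and 8-point standard curves in duplicate.

Expression model: probe-level log2 means are drawn from
Normal(baseline_log2_mean, baseline_log2_sd) and per-sample Gaussian noise
with SD ``noise_log2_sd`` is added.  A planted effect shifts the log2 values
of one annotation group by log2(fold change), so the ratio of linear-scale
group means converges to the requested fold change (the log-normal Jensen
factor is common to both groups and cancels).  All other probes are null.

qPCR model: each sample carries a log-normal loading factor shared by all
genes; reference genes track it with only small measurement noise (hence
geNorm-stable), targets add biological noise and, for planted genes, a
class-specific fold change.  Cq values follow the amplicon's standard curve
Cq = intercept + slope * log10(quantity) with slope = -1/log10(1 + E), plus
replicate-level noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .qpcr import QPCRDataset

# Set A composition: (origin, mutation_class, count)
SET_A_COMPOSITION: tuple[tuple[str, str, int], ...] = (
    ("hereditary", "MEN2A-like", 16),
    ("hereditary", "MEN2B-like", 2),
    ("hereditary", "other", 4),
    ("sporadic", "MEN2A-like", 5),
    ("sporadic", "MEN2B-like", 7),
    ("sporadic", "other", 7),
    ("sporadic", "RET-negative", 15),
    ("sporadic", "unknown", 4),
)

SET_B_COMPOSITION: tuple[tuple[str, str, int], ...] = (
    ("hereditary", "MEN2A-like", 16),
    ("sporadic", "MEN2A-like", 5),
    ("hereditary", "MEN2B-like", 2),
    ("sporadic", "MEN2B-like", 7),
)


@dataclass(frozen=True)
class PlantedEffect:
    """A probe whose ``group`` samples are shifted by log2(fold_change).

    ``column`` is the annotation column defining the contrast
    ("mutation_class" or "origin"); ``group`` is the up- (fold_change > 1)
    or down-shifted (fold_change < 1) class, the numerator of the fold
    change against any unshifted class.
    """

    probe_id: str
    fold_change: float
    column: str = "mutation_class"
    group: str = "MEN2A-like"


# Default planted signature: the four classifier genes with their fold
# changes between MEN2A-like and MEN2B-like tumours (MEN2A in the numerator).
DEFAULT_SIGNATURE: tuple[PlantedEffect, ...] = (
    PlantedEffect("7991186_NTRK3", 0.21),
    PlantedEffect("8062395_NNAT", 6.54),
    PlantedEffect("8128087_GABRR1", 0.18),
    PlantedEffect("8066347_PTPRT", 4.06),
)


@dataclass
class SimConfig:
    """Configuration of the synthetic microarray cohort.

    Noise and baseline defaults are modelling assumptions typical of
    RMA-summarised tumour data (log2 means centred near 6 with probe-level
    spread 1.5; within-group biological SD 0.8 log2 units), not measured
    study values.
    """

    n_probes: int = 10000
    composition: tuple[tuple[str, str, int], ...] = SET_A_COMPOSITION
    planted_effects: tuple[PlantedEffect, ...] = DEFAULT_SIGNATURE
    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 1.5
    noise_log2_sd: float = 0.8
    n_control_probes: int = 50
    control_prefix: str = "AFFX"
    seed: int = 0

    @classmethod
    def set_b(cls, **kwargs) -> "SimConfig":
        """Mutation-contrast cohort only (21 MEN2A-like vs 9 MEN2B-like)."""
        return cls(composition=SET_B_COMPOSITION, **kwargs)

    @property
    def n_samples(self) -> int:
        return sum(c for _, _, c in self.composition)

    def validate(self) -> None:
        if self.n_probes <= 0:
            raise ValueError("n_probes must be positive")
        if self.baseline_log2_sd <= 0 or self.noise_log2_sd <= 0:
            raise ValueError("scale parameters must be positive")
        if any(c <= 0 for _, _, c in self.composition):
            raise ValueError("class counts must be positive")
        ids = [e.probe_id for e in self.planted_effects]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate planted probe ids")
        if len(ids) > self.n_probes:
            raise ValueError("more planted effects than probes")
        groups = {(o, m) for o, m, _ in self.composition}
        for eff in self.planted_effects:
            if eff.fold_change <= 0:
                raise ValueError(f"planted fold change must be > 0: {eff}")
            if eff.column == "origin":
                known = {o for o, _ in groups}
            elif eff.column == "mutation_class":
                known = {m for _, m in groups}
            else:
                raise ValueError(f"unknown contrast column {eff.column!r}")
            if eff.group not in known:
                raise ValueError(
                    f"planted effect targets absent class {eff.group!r}"
                )


def _make_annotation(composition, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    i = 0
    for origin, mclass, count in composition:
        for _ in range(count):
            i += 1
            rows.append(
                {"sample_id": f"MTC{i:03d}", "origin": origin,
                 "mutation_class": mclass, "family_id": ""}
            )
    ann = pd.DataFrame(rows).set_index("sample_id")
    # two families of two samples each among the hereditary cases
    hered = ann.index[ann["origin"] == "hereditary"]
    for fam, pair in enumerate(np.array_split(hered[:4], 2), start=1):
        ann.loc[pair, "family_id"] = f"FAM{fam}"
    return ann


def generate_expression_set(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a (probes x samples) log2 matrix and its sample annotation.

    Deterministic for a fixed config: the same seed yields an identical
    matrix.  Planted probes keep the ids given in the config; the remaining
    probes get synthetic 7-digit ids, plus ``n_control_probes`` control
    probe sets named with ``control_prefix``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ann = _make_annotation(config.composition, rng)
    n_samples = len(ann)

    planted_ids = [e.probe_id for e in config.planted_effects]
    n_null = config.n_probes - len(planted_ids)
    probe_ids = planted_ids + [f"{9000000 + i}" for i in range(1, n_null + 1)]
    probe_ids += [
        f"{config.control_prefix}-{i}" for i in range(1, config.n_control_probes + 1)
    ]

    n_total = len(probe_ids)
    probe_means = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n_total)
    values = probe_means[:, None] + rng.normal(
        0.0, config.noise_log2_sd, (n_total, n_samples)
    )
    matrix = pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"),
                          columns=ann.index.rename(None))
    for eff in config.planted_effects:
        mask = (ann[eff.column] == eff.group).to_numpy()
        matrix.loc[eff.probe_id, mask] += np.log2(eff.fold_change)
    return matrix, ann


# ---------------------------------------------------------------------------
# qPCR cohort
# ---------------------------------------------------------------------------

# Nine of the ten mutation-contrast genes were assayable by qPCR (NTRK3's
# amplicons failed); NNAT and CDC14B carry the validated fold changes.
DEFAULT_QPCR_TARGETS: tuple[str, ...] = (
    "NALCN", "ZC3H12C", "HMGA2", "HLA-DRB5", "PDGFRL",
    "CDC14B", "NNAT", "ZNF658", "HSD17B14",
)
DEFAULT_REFERENCE_GENES: tuple[str, ...] = ("EIF3S10", "HADHA", "UBE2D2")
DEFAULT_QPCR_EFFECTS: dict[str, float] = {"NNAT": 3.3, "CDC14B": 2.8}


@dataclass
class QPCRSimConfig:
    """Configuration of the synthetic qPCR validation cohort.

    ``planted_fold_changes`` maps target genes to the linear fold change of
    the first class over the second (unlisted targets are null).
    ``efficiency`` = 1.0 means perfect doubling per cycle.
    """

    target_genes: tuple[str, ...] = DEFAULT_QPCR_TARGETS
    reference_genes: tuple[str, ...] = DEFAULT_REFERENCE_GENES
    planted_fold_changes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_QPCR_EFFECTS)
    )
    class_sizes: tuple[tuple[str, int], ...] = (("MEN2A-like", 16), ("MEN2B-like", 9))
    efficiency: float = 1.0
    intercept_cq: float = 24.0
    n_dilutions: int = 8
    dilution_factor: float = 10.0
    n_replicates: int = 2
    loading_log2_sd: float = 1.0
    target_noise_log2_sd: float = 0.8
    reference_noise_log2_sd: float = 0.05
    cq_replicate_sd: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if len(self.reference_genes) < 2:
            raise ValueError("geNorm needs at least 2 reference genes")
        if self.n_dilutions < 3:
            raise ValueError("standard curve needs >= 3 dilution points")
        if self.efficiency <= 0:
            raise ValueError("amplification efficiency must be positive")
        unknown = set(self.planted_fold_changes) - set(self.target_genes)
        if unknown:
            raise ValueError(f"planted genes not among targets: {sorted(unknown)}")
        if any(fc <= 0 for fc in self.planted_fold_changes.values()):
            raise ValueError("planted fold changes must be > 0")


def generate_qpcr_dataset(config: QPCRSimConfig) -> QPCRDataset:
    """Draw a synthetic qPCR validation cohort (see module docstring)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    slope = -1.0 / np.log10(1.0 + config.efficiency)

    rows = []
    i = 0
    for mclass, count in config.class_sizes:
        for _ in range(count):
            i += 1
            rows.append(
                {"sample_id": f"VAL{i:03d}", "origin": "sporadic",
                 "mutation_class": mclass, "family_id": ""}
            )
    ann = pd.DataFrame(rows).set_index("sample_id")
    first_class = config.class_sizes[0][0]

    loading = 2.0 ** rng.normal(0.0, config.loading_log2_sd, len(ann))
    genes = list(config.reference_genes) + list(config.target_genes)
    gene_scale = {g: 2.0 ** rng.normal(0.0, 1.0) for g in genes}

    records = []
    for g in genes:
        is_ref = g in config.reference_genes
        sd = config.reference_noise_log2_sd if is_ref else config.target_noise_log2_sd
        noise = 2.0 ** rng.normal(0.0, sd, len(ann))
        q = gene_scale[g] * loading * noise
        if not is_ref and g in config.planted_fold_changes:
            shift = (ann["mutation_class"] == first_class).to_numpy()
            q = q * np.where(shift, config.planted_fold_changes[g], 1.0)
        cq_mean = config.intercept_cq + slope * np.log10(q)
        for rep in range(1, config.n_replicates + 1):
            cq = cq_mean + rng.normal(0.0, config.cq_replicate_sd, len(ann))
            for sample, value in zip(ann.index, cq):
                records.append(
                    {"sample_id": sample, "gene": g, "replicate": rep,
                     "cq": float(value)}
                )

    curve_rows = []
    for g in genes:
        for step in range(config.n_dilutions):
            quantity = config.dilution_factor ** (-step)
            cq_mean = config.intercept_cq + slope * np.log10(quantity)
            for rep in range(1, config.n_replicates + 1):
                curve_rows.append(
                    {"gene": g, "dilution_step": step, "quantity": quantity,
                     "replicate": rep,
                     "cq": float(cq_mean + rng.normal(0.0, config.cq_replicate_sd))}
                )

    return QPCRDataset(
        records=pd.DataFrame(records),
        standard_curves=pd.DataFrame(curve_rows),
        reference_genes=list(config.reference_genes),
        annotation=ann,
    )


# ---------------------------------------------------------------------------
# YAML config round-trip (CLI support)
# ---------------------------------------------------------------------------

def config_to_yaml(config: SimConfig, path) -> None:
    data = asdict(config)
    data["composition"] = [list(t) for t in config.composition]
    data["planted_effects"] = [asdict(e) for e in config.planted_effects]
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def config_from_yaml(path) -> SimConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    data["composition"] = tuple(tuple(t) for t in data.get("composition", SET_A_COMPOSITION))
    data["planted_effects"] = tuple(
        PlantedEffect(**e) for e in data.get("planted_effects", [])
    )
    return SimConfig(**data)
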