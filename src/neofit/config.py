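"""Run and simulation configuration.

Two dataclasses hold every tunable of the analysis: :class:`RunConfig` for
the scoring/summary/comparison stages and :class:`SimConfig` for the
synthetic-cohort generator. Both serialize losslessly to YAML so a run can
be reproduced from its config file plus a seed.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple

import yaml

AVERAGING_SETS = ("immunogenic", "binding")
WILCOXON_MODES = ("exact", "normal", "auto")


class ConfigError(ValueError):
    """Raised when a configuration value violates its contract."""


@dataclass
class RunConfig:
    """Parameters of the neoantigen scoring and cohort comparison.

    Attributes
    ----------
    kd_binding_threshold_nM:
        A mutant 9-mer is a *binding* neoantigen when its best dissociation
        constant is strictly below this value (nM).
    tcr_a:
        Horizontal displacement of the TCR binding curve (alignment-score
        units).
    tcr_k:
        Steepness of the TCR binding curve at ``tcr_a``.
    r_stringent_threshold:
        Recognition-potential cutoff defining the stringent neoantigen
        subset (R >= threshold).
    min_immunogenic_for_eligibility:
        A sample enters between-group strength comparisons only with at
        least this many immunogenic neoantigens.
    wt_kd_cap_nM:
        Optional cap applied to the wild-type Kd before forming the
        amplitude; ``None`` disables the correction.
    averaging_set:
        Which records per-sample means are taken over: ``"immunogenic"``
        (default) or ``"binding"``.
    wilcoxon_mode:
        Rank-sum p-value mode used by the group comparison: ``"normal"``
        (large-sample approximation without continuity correction, the
        convention of common statistical packages for this test),
        ``"exact"`` (full enumeration) or ``"auto"``.
    drop_magnitude_outliers:
        When true, eligible samples whose maximum fitness cost sits two or
        more orders of magnitude below the cohort mean are excluded.
    """

    kd_binding_threshold_nM: float = 500.0
    tcr_a: float = 26.0
    tcr_k: float = 4.87
    r_stringent_threshold: float = 0.01
    min_immunogenic_for_eligibility: int = 2
    wt_kd_cap_nM: Optional[float] = None
    rng_seed: int = 0
    averaging_set: str = "immunogenic"
    wilcoxon_mode: str = "normal"
    drop_magnitude_outliers: bool = False
    outlier_fold: float = 100.0

    def __post_init__(self) -> None:
        if self.kd_binding_threshold_nM <= 0:
            raise ConfigError("kd_binding_threshold_nM must be > 0")
        if self.tcr_k <= 0:
            raise ConfigError("tcr_k must be > 0")
        if not 0.0 <= self.r_stringent_threshold <= 1.0:
            raise ConfigError("r_stringent_threshold must lie in [0, 1]")
        if self.min_immunogenic_for_eligibility < 0:
            raise ConfigError("min_immunogenic_for_eligibility must be >= 0")
        if self.wt_kd_cap_nM is not None and self.wt_kd_cap_nM <= 0:
            raise ConfigError("wt_kd_cap_nM must be > 0 or None")
        if self.averaging_set not in AVERAGING_SETS:
            raise ConfigError(f"averaging_set must be one of {AVERAGING_SETS}")
        if self.wilcoxon_mode not in WILCOXON_MODES:
            raise ConfigError(f"wilcoxon_mode must be one of {WILCOXON_MODES}")
        if self.outlier_fold <= 1:
            raise ConfigError("outlier_fold must be > 1")

    def to_yaml(self, path: str | Path) -> None:
        _dump_yaml(self, path)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return _load_yaml(cls, path)


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort generator.

    The generator emulates a two-group skin-lesion cohort: per-sample
    somatic burdens spanning two orders of magnitude, lognormal peptide:MHC
    dissociation constants calibrated to a target binding fraction, a small
    reference set of known T-cell epitopes, lognormal per-transcript RPKM
    expression, and a group-B escape effect that suppresses expression of
    each sample's strongest-fitness neoantigens.
    """

    n_samples_group_a: int = 3
    n_samples_group_b: int = 4
    mutation_burden_range: Tuple[int, int] = (50, 5000)
    fraction_nonsynonymous: float = 0.7
    n_proteins: int = 100
    protein_length_range: Tuple[int, int] = (250, 450)
    n_epitopes: int = 20
    epitope_source_proteins: int = 3
    alleles: Tuple[str, ...] = (
        "HLA-A*01:01",
        "HLA-A*02:01",
        "HLA-B*07:02",
        "HLA-B*08:01",
        "HLA-C*07:01",
        "HLA-C*07:02",
    )
    kd_sigma: float = 1.5
    kd_mu: Optional[float] = None  # None -> calibrated from binding_fraction_target
    binding_fraction_target: float = 0.03
    kd_mt_wt_correlation: float = 0.9
    wt_log_kd_shift: float = -0.7
    expression_mu: float = 2.0
    expression_sigma: float = 1.0
    suppression_effect: float = 0.05
    suppression_top_k: int = 3
    indel_fraction: float = 0.02
    near_indel_snv_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        self.mutation_burden_range = tuple(self.mutation_burden_range)  # type: ignore[assignment]
        self.protein_length_range = tuple(self.protein_length_range)  # type: ignore[assignment]
        self.alleles = tuple(self.alleles)  # type: ignore[assignment]
        lo, hi = self.mutation_burden_range
        if not (0 <= lo <= hi):
            raise ConfigError("mutation_burden_range must be ordered and non-negative")
        plo, phi = self.protein_length_range
        if not (21 <= plo <= phi):
            raise ConfigError("protein_length_range must be ordered with min >= 21")
        if not 0.0 <= self.fraction_nonsynonymous <= 1.0:
            raise ConfigError("fraction_nonsynonymous must lie in [0, 1]")
        if not 0.0 <= self.suppression_effect <= 1.0:
            raise ConfigError("suppression_effect must lie in [0, 1]")
        if not 0.0 < self.binding_fraction_target < 1.0:
            raise ConfigError("binding_fraction_target must lie in (0, 1)")
        if self.kd_sigma <= 0:
            raise ConfigError("kd_sigma must be > 0")
        if not 0.0 <= self.kd_mt_wt_correlation <= 1.0:
            raise ConfigError("kd_mt_wt_correlation must lie in [0, 1]")
        if self.suppression_top_k < 0:
            raise ConfigError("suppression_top_k must be >= 0")
        if not 0 < self.epitope_source_proteins <= self.n_proteins and self.n_proteins > 0:
            raise ConfigError("epitope_source_proteins must lie in [1, n_proteins]")

    def to_yaml(self, path: str | Path) -> None:
        _dump_yaml(self, path)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        return _load_yaml(cls, path)


def _dump_yaml(cfg, path: str | Path) -> None:
    data = dataclasses.asdict(cfg)
    # YAML has no tuple type; tuples come back as lists and are re-tupled on load
    data = {k: list(v) if isinstance(v, tuple) else v for k, v in data.items()}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def _load_yaml(cls, path: str | Path):
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config file must contain a mapping")
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
    return cls(**data)
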