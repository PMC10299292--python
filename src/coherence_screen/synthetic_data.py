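"""Synthetic expression/phenotype generator with planted ground truth.

Generates log2-scale case/control expression matrices in which a configurable
set of "planted" genes is correlated with an anchor gene within the case
group, together with clinical scores (MMSE, NFT) linearly coupled to a
designated planted gene.  Every downstream stage of the pipeline can be
tested against the returned :class:`GroundTruth`.

Model
-----
Each gene g gets a baseline mean ``mu_g`` drawn uniformly from
``baseline_range``.  Control values are ``mu_g + noise_sd * e`` with
``e ~ N(0, 1)`` i.i.d.  For the anchor and each planted gene, case values are
additionally shifted by ``case_shift``.  Within the case group, a planted
gene g shares the anchor's noise component:

    x_g(case) = mu_g + case_shift + noise_sd * (r * e_anchor + sqrt(1-r^2) * e_g)

so the population correlation between g and the anchor across case samples is
exactly ``r = planted_corr``.  Control values of planted genes are
independent draws.  Non-planted, non-anchor genes are independent noise
everywhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from coherence_screen.dataio import DataIOError, ExpressionMatrix, PhenotypeTable

#: Gene-name fixture for simulated universes (anchor writer + common
#: methylation-machinery symbols); purely cosmetic naming.
DEFAULT_GENE_NAMES = [
    "METTL3", "METTL14", "METTL16", "RBM15", "RBM15B", "WTAP", "VIRMA",
    "ZC3H13", "FTO", "ALKBH5", "HNRNPC", "HNRNPA2B1", "YTHDF1", "YTHDF2",
    "YTHDF3", "YTHDC1", "YTHDC2", "IGF2BP1", "IGF2BP2", "IGF2BP3",
    "NDUFA10", "SDHA", "GPI", "NDUFC2",
]


class SyntheticConfigError(ValueError):
    """Raised when a SyntheticConfig violates an invariant."""


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic data generator.

    Defaults emulate a 74-control / 87-case cohort with an anchor gene
    "METTL3", eight planted coherent genes (the first, "NDUFA10", drives the
    clinical scores), and mild downregulation of the anchor and planted set
    in cases.
    """

    n_genes: int = 120
    n_control: int = 74
    n_case: int = 87
    anchor_name: str = "METTL3"
    planted_genes: list[str] = field(default_factory=lambda: [
        "NDUFA10", "SDHA", "GPI", "NDUFC2", "YTHDC1", "HNRNPC", "YTHDF2", "COX5A",
    ])
    planted_corr: float = 0.9
    case_shift: float = -1.0
    noise_sd: float = 1.0
    baseline_range: tuple[float, float] = (6.0, 10.0)
    clinical_gene: str | None = None  # defaults to planted_genes[0]
    clinical_slope_mmse: float = 2.0
    clinical_slope_nft: float = -1.0
    mmse_intercept: float = 2.0
    nft_intercept: float = 10.0
    control_mmse: float = 29.0
    control_nft: float = 0.0
    clinical_noise_sd: float = 1.0
    clip_scores: bool = True
    severity_strata: tuple[int, int, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_genes < 1:
            raise SyntheticConfigError("n_genes must be positive")
        if self.n_control < 2 or self.n_case < 2:
            raise SyntheticConfigError("n_control and n_case must each be >= 2")
        if not (0.0 <= self.planted_corr <= 1.0):
            raise SyntheticConfigError("planted_corr must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise SyntheticConfigError("noise_sd must be > 0")
        if self.clinical_noise_sd < 0:
            raise SyntheticConfigError("clinical_noise_sd must be >= 0")
        if self.anchor_name in self.planted_genes:
            raise SyntheticConfigError(
                "planted_genes must not contain the anchor gene "
                f"'{self.anchor_name}'"
            )
        if len(set(self.planted_genes)) != len(self.planted_genes):
            raise SyntheticConfigError("planted_genes contains duplicates")
        # anchor + planted must fit in the universe
        if len(self.planted_genes) + 1 > self.n_genes:
            raise SyntheticConfigError(
                "n_genes too small for anchor plus planted_genes"
            )
        if self.severity_strata is not None:
            strata = tuple(int(x) for x in self.severity_strata)
            if len(strata) != 3 or any(x < 0 for x in strata):
                raise SyntheticConfigError(
                    "severity_strata must be three non-negative counts"
                )
            if sum(strata) != self.n_case:
                raise SyntheticConfigError(
                    f"severity_strata {strata} must sum to n_case={self.n_case}"
                )
            self.severity_strata = strata
        if self.clinical_gene is not None and (
            self.clinical_gene not in self.planted_genes
        ):
            raise SyntheticConfigError(
                f"clinical_gene '{self.clinical_gene}' is not a planted gene"
            )

    @property
    def designated_clinical_gene(self) -> str:
        if self.clinical_gene is not None:
            return self.clinical_gene
        if not self.planted_genes:
            raise SyntheticConfigError(
                "no planted genes: cannot designate a clinical driver gene"
            )
        return self.planted_genes[0]

    def gene_universe(self) -> list[str]:
        """Gene names: anchor first, then planted, then filler names."""
        names = [self.anchor_name] + list(self.planted_genes)
        pool = [g for g in DEFAULT_GENE_NAMES if g not in names]
        i = 1
        while len(names) < self.n_genes:
            if pool:
                names.append(pool.pop(0))
            else:
                candidate = f"GENE{i:05d}"
                if candidate not in names:
                    names.append(candidate)
                i += 1
        return names

    @classmethod
    def from_file(cls, path: str | Path) -> "SyntheticConfig":
        """Load a config from a YAML or JSON file."""
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) if path.suffix in (".yml", ".yaml") else json.load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SyntheticConfig":
        if not isinstance(raw, dict):
            raise SyntheticConfigError("config file must contain a mapping")
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise SyntheticConfigError(f"unknown config keys: {sorted(unknown)}")
        if "severity_strata" in raw and raw["severity_strata"] is not None:
            raw = dict(raw)
            raw["severity_strata"] = tuple(raw["severity_strata"])
        if "baseline_range" in raw and raw["baseline_range"] is not None:
            raw = dict(raw)
            raw["baseline_range"] = tuple(raw["baseline_range"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["severity_strata"] is not None:
            d["severity_strata"] = list(d["severity_strata"])
        d["baseline_range"] = list(d["baseline_range"])
        return d


@dataclass
class GroundTruth:
    """What was planted: genes, realized case-group anchor correlations, slopes."""

    anchor: str
    planted_genes: list[str]
    realized_corr: dict[str, float]
    clinical_gene: str
    slope_mmse: float
    slope_nft: float

    def __post_init__(self) -> None:
        if set(self.realized_corr) != set(self.planted_genes):
            raise ValueError("realized_corr keys must match planted_genes")


def gse5281_like(**overrides) -> SyntheticConfig:
    """Config emulating a 74-control / 87-case cohort structure."""
    return SyntheticConfig(**{**dict(n_control=74, n_case=87), **overrides})


def gse1297_like(**overrides) -> SyntheticConfig:
    """Config emulating a 9-control / 22-case cohort with 7/8/7 severity strata."""
    defaults = dict(n_control=9, n_case=22, severity_strata=(7, 8, 7))
    return SyntheticConfig(**{**defaults, **overrides})


def generate_expression(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, PhenotypeTable, GroundTruth]:
    """Generate the expression matrix, phenotype table, and ground truth.

    Deterministic for a fixed ``config.seed``; see the module docstring for
    the generative model.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = config.gene_universe()
    for g in config.planted_genes:
        if g not in genes:
            raise SyntheticConfigError(f"planted gene '{g}' not in gene universe")

    n_ctrl, n_case = config.n_control, config.n_case
    sample_ids = [f"CTRL{i + 1:03d}" for i in range(n_ctrl)] + [
        f"CASE{i + 1:03d}" for i in range(n_case)
    ]
    lo, hi = config.baseline_range
    mu = rng.uniform(lo, hi, size=len(genes))

    values = np.empty((len(genes), n_ctrl + n_case))
    gidx = {g: i for i, g in enumerate(genes)}
    planted = set(config.planted_genes)
    r = config.planted_corr
    root = float(np.sqrt(max(0.0, 1.0 - r * r)))

    # anchor case noise is shared with planted genes to impose the correlation
    e_anchor_case = rng.standard_normal(n_case)
    for i, g in enumerate(genes):
        ctrl = mu[i] + config.noise_sd * rng.standard_normal(n_ctrl)
        if g == config.anchor_name:
            case = mu[i] + config.case_shift + config.noise_sd * e_anchor_case
        elif g in planted:
            e_g = rng.standard_normal(n_case)
            case = mu[i] + config.case_shift + config.noise_sd * (
                r * e_anchor_case + root * e_g
            )
        else:
            case = mu[i] + config.noise_sd * rng.standard_normal(n_case)
        values[i] = np.concatenate([ctrl, case])

    expr = ExpressionMatrix(genes, sample_ids, values)

    case_block = values[:, n_ctrl:]
    anchor_case = case_block[gidx[config.anchor_name]]
    realized = {
        g: float(np.corrcoef(case_block[gidx[g]], anchor_case)[0, 1])
        for g in config.planted_genes
    }
    truth = GroundTruth(
        anchor=config.anchor_name,
        planted_genes=list(config.planted_genes),
        realized_corr=realized,
        clinical_gene=config.designated_clinical_gene,
        slope_mmse=config.clinical_slope_mmse,
        slope_nft=config.clinical_slope_nft,
    )
    phen = generate_clinical(config, expr)
    return expr, phen, truth


def generate_clinical(config: SyntheticConfig, expr: ExpressionMatrix) -> PhenotypeTable:
    """Generate the phenotype table with MMSE/NFT coupled to the designated gene.

    Case samples get ``score = intercept + slope * x_gene + noise``; controls
    sit at the healthy ceiling (MMSE) / floor (NFT).  Severity strata, when
    configured, are assigned by case MMSE rank: the lowest-MMSE cases are
    labeled severe, then moderate, then mild.
    """
    config.validate()
    n_ctrl, n_case = config.n_control, config.n_case
    if expr.n_samples != n_ctrl + n_case:
        raise DataIOError(
            f"expression matrix has {expr.n_samples} samples but config "
            f"specifies {n_ctrl + n_case}"
        )
    # clinical noise uses a stream decoupled from the expression stream so
    # that generate_expression + generate_clinical stay reproducible jointly
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    driver = config.designated_clinical_gene
    case_ids = expr.sample_ids[n_ctrl:]
    x = expr.gene_values(driver, case_ids)

    mmse_case = (
        config.mmse_intercept
        + config.clinical_slope_mmse * x
        + config.clinical_noise_sd * rng.standard_normal(n_case)
    )
    nft_case = (
        config.nft_intercept
        + config.clinical_slope_nft * x
        + config.clinical_noise_sd * rng.standard_normal(n_case)
    )
    if config.clip_scores:
        mmse_case = np.clip(mmse_case, 0.0, 30.0)
        nft_case = np.clip(nft_case, 0.0, None)

    severity: list[str | None] = [None] * (n_ctrl + n_case)
    if config.severity_strata is not None:
        n_mild, n_moderate, n_severe = config.severity_strata
        order = np.argsort(mmse_case, kind="stable")  # ascending: worst first
        labels = ["severe"] * n_severe + ["moderate"] * n_moderate + ["mild"] * n_mild
        for pos, lab in zip(order, labels):
            severity[n_ctrl + pos] = lab

    mmse = [config.control_mmse] * n_ctrl + [float(v) for v in mmse_case]
    nft = [config.control_nft] * n_ctrl + [float(v) for v in nft_case]
    return PhenotypeTable(
        sample_ids=list(expr.sample_ids),
        group=["control"] * n_ctrl + ["case"] * n_case,
        severity=severity,
        mmse=mmse,
        nft=nft,
    )
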