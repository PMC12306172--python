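"""Synthetic two-enterotype community and cohort generator.

The generator emulates the statistical structure the downstream analysis
assumes, not any real cohort: genus-level count tables are drawn from a
Dirichlet-multinomial mixture of two archetype communities, one dominated
by *Phocaeicola* and one by *Segatella*, with per-sample sequencing depth
varying uniformly. Sex role is coupled to enterotype membership through a
logistic link with configurable odds ratios (versatile and receptive-only
each against the insertive-only reference); the intercept is calibrated by
root finding so the marginal cluster frequency matches the requested
prior. All other behavioural covariates are drawn independently of the
cluster, and age and BMI are Gaussian.

Each archetype places mass ``delta`` on its dominant genus and spreads the
remainder over the other genera by a rank-abundance power law (exponent
1.5), sharing the tail order between archetypes but demoting the rival
dominant genus to the lowest rank — so ``delta`` cleanly controls the
between-archetype contrast, and the long tail produces the singletons and
doubletons that exercise the richness estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import bisect
from scipy.special import expit

from .io import (
    AbundanceTable,
    BOOL_FIELDS,
    CONDOM_LEVELS,
    PARTNER_LEVELS,
    SEX_ROLE_LEVELS,
)

PHOCAEICOLA = "Phocaeicola"
SEGATELLA = "Segatella"


@dataclass
class GeneratorConfig:
    """Study-scale defaults: a 95-sample cohort with a 43/52 cluster split,
    sex-role marginals of 0.35/0.48/0.17 and a true versatile odds ratio
    of 6.1 for membership in the Segatella-dominated cluster."""

    n_samples: int = 95
    n_genera: int = 120
    dominants: tuple[str, str] = (PHOCAEICOLA, SEGATELLA)
    delta: float = 0.35                # dominant-genus mass per archetype
    tail_exponent: float = 1.5         # rank-abundance power law
    dirichlet_concentration: float = 50.0
    depth_range: tuple[int, int] = (20000, 60000)
    cluster_prior: float = 52 / 95     # P(Segatella-dominated)
    role_probs: tuple[float, float, float] = (0.35, 0.48, 0.17)
    or_versatile: float = 6.1
    or_receptive: float = 1.5
    age_mean: float = 31.0
    age_sd: float = 8.4
    bmi_mean: float = 20.9
    bmi_sd: float = 3.44
    partner_probs: tuple[float, ...] = (0.368, 0.463, 0.032, 0.137)
    condom_probs: tuple[float, ...] = (0.063, 0.189, 0.748)
    bool_probs: dict = field(default_factory=lambda: {
        "commercial_sex": 0.063, "group_sex": 0.084,
        "std": 0.074, "illicit_drug": 0.074,
    })
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 2 or self.n_genera < 3:
            raise ValueError("need n_samples >= 2 and n_genera >= 3")
        if not 0 < self.delta < 1:
            raise ValueError("delta must lie in (0, 1)")
        if not 0 < self.cluster_prior < 1:
            raise ValueError("cluster_prior must lie in (0, 1)")
        if self.or_versatile <= 0 or self.or_receptive <= 0:
            raise ValueError("odds ratios must be positive")
        if self.depth_range[0] > self.depth_range[1] or self.depth_range[0] < 1:
            raise ValueError("invalid depth range")
        for name, probs in (("role_probs", self.role_probs),
                            ("partner_probs", self.partner_probs),
                            ("condom_probs", self.condom_probs)):
            if abs(sum(probs) - 1.0) > 1e-6 or min(probs) < 0:
                raise ValueError(f"{name} must be a probability vector")
        if self.dirichlet_concentration <= 0:
            raise ValueError("dirichlet_concentration must be positive")


@dataclass
class SyntheticDataset:
    table: AbundanceTable
    metadata: pd.DataFrame
    true_labels: np.ndarray          # 0 = Phocaeicola-, 1 = Segatella-dominated
    config: GeneratorConfig


def genus_names(config: GeneratorConfig) -> list[str]:
    others = [f"Genus_{i:03d}" for i in range(3, config.n_genera + 1)]
    return [config.dominants[0], config.dominants[1], *others]


def archetype_compositions(config: GeneratorConfig) -> np.ndarray:
    """The two archetype probability vectors, rows summing to 1."""
    g = config.n_genera
    comps = np.zeros((2, g))
    for c in (0, 1):
        rival = 1 - c
        # tail order: shared genera 2..g-1, rival dominant last
        tail = list(range(2, g)) + [rival]
        ranks = np.arange(1, len(tail) + 1, dtype=float)
        w = ranks ** -config.tail_exponent
        w *= (1.0 - config.delta) / w.sum()
        comps[c, c] = config.delta
        comps[c, tail] = w
    return comps


def calibrate_intercept(config: GeneratorConfig, tol: float = 1e-10) -> float:
    """Intercept beta0 of the role->cluster logistic link such that the
    marginal P(Segatella-dominated) equals ``cluster_prior``."""
    config.validate()
    probs = np.asarray(config.role_probs)
    shifts = np.array([0.0, np.log(config.or_versatile), np.log(config.or_receptive)])

    def marginal(b0: float) -> float:
        return float(probs @ expit(b0 + shifts)) - config.cluster_prior

    lo, hi = -50.0, 50.0
    if marginal(lo) > 0 or marginal(hi) < 0:
        raise ValueError(
            "cluster_prior unattainable for these odds ratios; feasible "
            f"range is ({probs @ expit(lo + shifts):.3g}, "
            f"{probs @ expit(hi + shifts):.3g})"
        )
    return float(bisect(marginal, lo, hi, xtol=tol))


def sample_roles_and_clusters(config: GeneratorConfig, rng: np.random.Generator
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Draw sex roles from the marginals and cluster membership from the
    calibrated logistic link. Returns (role index 0/1/2, cluster 0/1)."""
    b0 = calibrate_intercept(config)
    shifts = np.array([0.0, np.log(config.or_versatile), np.log(config.or_receptive)])
    roles = rng.choice(3, size=config.n_samples, p=config.role_probs)
    p_seg = expit(b0 + shifts[roles])
    clusters = (rng.random(config.n_samples) < p_seg).astype(int)
    return roles, clusters


def generate(config: GeneratorConfig | None = None) -> SyntheticDataset:
    """Generate a full synthetic dataset (count table, metadata, truth)."""
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    roles, clusters = sample_roles_and_clusters(config, rng)
    comps = archetype_compositions(config)
    alpha = config.dirichlet_concentration * comps
    # Dirichlet with tiny concentration entries: draw per-component gammas
    depths = rng.integers(config.depth_range[0], config.depth_range[1] + 1,
                          size=config.n_samples)
    counts = np.zeros((config.n_genera, config.n_samples), dtype=np.int64)
    for i in range(config.n_samples):
        gam = rng.gamma(np.clip(alpha[clusters[i]], 1e-12, None))
        if gam.sum() == 0:
            gam = alpha[clusters[i]]
        composition = gam / gam.sum()
        counts[:, i] = rng.multinomial(depths[i], composition)

    sample_ids = [f"S{i + 1:03d}" for i in range(config.n_samples)]
    table = AbundanceTable(genus_names(config), sample_ids, counts)

    age = np.clip(rng.normal(config.age_mean, config.age_sd, config.n_samples), 18, None)
    bmi = np.clip(rng.normal(config.bmi_mean, config.bmi_sd, config.n_samples), 14, None)
    meta = pd.DataFrame({
        "sample_id": sample_ids,
        "age": np.round(age, 1),
        "bmi": np.round(bmi, 1),
        "sex_role": [SEX_ROLE_LEVELS[r] for r in roles],
        "partners": rng.choice(PARTNER_LEVELS, size=config.n_samples,
                               p=config.partner_probs),
        "condom": rng.choice(CONDOM_LEVELS, size=config.n_samples,
                             p=config.condom_probs),
    })
    for name in BOOL_FIELDS:
        meta[name] = rng.random(config.n_samples) < config.bool_probs[name]
    meta = meta.set_index("sample_id")
    return SyntheticDataset(table, meta, clusters, config)


def config_to_dict(config: GeneratorConfig) -> dict:
    d = asdict(config)
    d["dominants"] = list(d["dominants"])
    d["depth_range"] = list(d["depth_range"])
    d["role_probs"] = list(d["role_probs"])
    d["partner_probs"] = list(d["partner_probs"])
    d["condom_probs"] = list(d["condom_probs"])
    return d
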