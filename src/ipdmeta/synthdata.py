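"""Seeded generator of synthetic pooled IPD for a diagnostic-accuracy
meta-analysis.

The generative family is binormal with a covariate effect: study ``i`` draws
a baseline nondiseased test mean ``mu0_i``, a disease effect
``delta_i ~ N(shift_mean, heterogeneity_sd^2)`` shared by all its diseased
subjects, and per-subject test results

    nondiseased:  y = mu0_i + gamma * z_age + N(0, sigma0^2)
    diseased:     y = mu0_i + gamma * z_age + delta_i + N(0, sigma1^2)

where ``z_age`` is the standardized continuous covariate.  Disease status is
Bernoulli with a per-study prevalence.  This is the simplest family that
exercises threshold effects, between-study heterogeneity and covariate
adjustment at the same time.  The default configuration emulates a
hypothetical meta-analysis of 15 primary studies reporting one continuous
index test, with one continuous and one categorical patient-level covariate
and no missing values.

Per-study random substreams are spawned deterministically from the seed, so
adding studies does not perturb earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import dataio
from .dataio import IPDDataset


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of the synthetic IPD generator.

    Units: test results and disease shifts are on the index-test scale
    (arbitrary units); the continuous covariate mimics age in years.
    """

    n_studies: int = 15
    n_range: tuple[int, int] = (50, 120)  # per-study sample size, uniform
    prevalence_range: tuple[float, float] = (0.25, 0.55)
    mu0_range: tuple[float, float] = (0.0, 1.0)  # nondiseased mean, uniform per study
    sigma0: float = 1.0  # nondiseased within-study SD
    sigma1: float = 1.0  # diseased within-study SD
    disease_shift_mean: float = 1.5  # mean test elevation in the diseased
    heterogeneity_sd: float = 0.3  # between-study SD of the disease shift
    covariate_effect: float = 0.5  # test-result change per SD of the continuous covariate
    age_mean: float = 55.0
    age_sd: float = 12.0
    sex_levels: tuple[str, ...] = ("female", "male")
    sex_probs: tuple[float, ...] = (0.5, 0.5)
    missing_rates: dict = field(default_factory=dict)  # column -> rate in [0, 1)
    seed: int = 20200909

    def validate(self) -> None:
        if self.n_studies < 1:
            raise ValueError("n_studies must be >= 1")
        for name in ("sigma0", "sigma1", "age_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.heterogeneity_sd < 0:
            raise ValueError("heterogeneity_sd must be >= 0")
        lo, hi = self.prevalence_range
        if not (0 < lo <= hi < 1):
            raise ValueError("prevalence_range must lie inside (0, 1)")
        if self.n_range[0] < 2 or self.n_range[0] > self.n_range[1]:
            raise ValueError("n_range must satisfy 2 <= lo <= hi")
        if len(self.sex_levels) != len(self.sex_probs) or abs(sum(self.sex_probs) - 1) > 1e-9:
            raise ValueError("sex_probs must match sex_levels and sum to 1")
        for col, rate in self.missing_rates.items():
            if not (0 <= rate < 1):
                raise ValueError(f"missing rate for {col!r} must lie in [0, 1)")


def generate_frame(config: SynthConfig = SynthConfig(), seed: int | None = None) -> pd.DataFrame:
    """Raw synthetic table in the input-file layout
    (Study, test.results, disease, age, sex)."""
    config.validate()
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    streams = root.spawn(config.n_studies)
    frames = []
    for i, ss in enumerate(streams, start=1):
        rng = np.random.default_rng(ss)
        n = int(rng.integers(config.n_range[0], config.n_range[1] + 1))
        prev = rng.uniform(*config.prevalence_range)
        mu0 = rng.uniform(*config.mu0_range)
        delta = rng.normal(config.disease_shift_mean, config.heterogeneity_sd)

        disease = (rng.random(n) < prev).astype(int)
        age = rng.normal(config.age_mean, config.age_sd, size=n)
        z_age = (age - config.age_mean) / config.age_sd
        sex = rng.choice(config.sex_levels, size=n, p=config.sex_probs)
        sigma = np.where(disease == 1, config.sigma1, config.sigma0)
        y = mu0 + config.covariate_effect * z_age + delta * disease + rng.normal(0, 1, n) * sigma

        frames.append(
            pd.DataFrame(
                {
                    "Study": f"Study {i:02d}",
                    "test.results": np.round(y, 4),
                    "disease": disease,
                    "age": np.round(age, 1),
                    "sex": sex,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)

    if config.missing_rates:
        rng = np.random.default_rng(root.spawn(1)[0])
        for col, rate in config.missing_rates.items():
            if col not in df.columns:
                raise ValueError(f"missing_rates names unknown column {col!r}")
            mask = rng.random(len(df)) < rate
            df.loc[mask, col] = np.nan
    return df


def generate_ipd(config: SynthConfig = SynthConfig(), seed: int | None = None) -> IPDDataset:
    """Generate a validated synthetic dataset (see :func:`generate_frame`)."""
    return dataio.from_frame(generate_frame(config, seed=seed))


def write_csv(path, config: SynthConfig = SynthConfig(), seed: int | None = None) -> Path:
    """Write a synthetic dataset in the standard CSV contract."""
    path = Path(path)
    generate_frame(config, seed=seed).to_csv(path, index=False)
    return path


def simulate_bivariate_tables(
    rng: np.random.Generator,
    k: int = 15,
    n_diseased: int = 100,
    n_nondiseased: int = 100,
    mu_a: float = 1.5,
    mu_b: float = 1.0,
    sd_a: float = 0.5,
    sd_b: float = 0.5,
    rho: float = -0.5,
):
    """Simulate per-study 2x2 tables from the bivariate normal model.

    Study ``i`` draws (logit Se_i, logit Sp_i) from a bivariate normal with
    means ``(mu_a, mu_b)``, SDs ``(sd_a, sd_b)`` and correlation ``rho``; cell
    counts are binomial given the study's Se/Sp.  Used as the known-truth
    generator for parameter-recovery checks.
    """
    from scipy.special import expit

    from .accuracy import ContingencyTable

    cov = np.array(
        [[sd_a**2, rho * sd_a * sd_b], [rho * sd_a * sd_b, sd_b**2]]
    )
    logits = rng.multivariate_normal([mu_a, mu_b], cov, size=k)
    tables = []
    for i, (la, lb) in enumerate(logits, start=1):
        tp = int(rng.binomial(n_diseased, expit(la)))
        tn = int(rng.binomial(n_nondiseased, expit(lb)))
        tables.append(
            ContingencyTable(
                study_id=i,
                threshold=np.nan,
                tp=tp,
                fn=n_diseased - tp,
                fp=n_nondiseased - tn,
                tn=tn,
            )
        )
    return tables


def simulate_hsroc_tables(
    rng: np.random.Generator,
    k: int = 15,
    n_diseased: int = 100,
    n_nondiseased: int = 100,
    lambda_: float = 2.5,
    theta: float = 0.25,
    beta: float = 0.3,
    sigma2_alpha: float = 0.5,
    sigma2_theta: float = 0.125,
):
    """Simulate per-study 2x2 tables from the HSROC generative model.

    Study ``i`` draws accuracy ``alpha_i ~ N(Lambda, sigma2_alpha)`` and
    threshold ``theta_i ~ N(Theta, sigma2_theta)`` (independent);

        logit Se_i = (alpha_i/2 + theta_i) * exp(-beta/2)
        logit Sp_i = (alpha_i/2 - theta_i) * exp(+beta/2)

    which inverts the bivariate-to-HSROC mapping, so a bivariate fit followed
    by conversion should recover the generating values.
    """
    from scipy.special import expit

    from .accuracy import ContingencyTable

    alphas = rng.normal(lambda_, np.sqrt(sigma2_alpha), size=k)
    thetas = rng.normal(theta, np.sqrt(sigma2_theta), size=k)
    tables = []
    for i, (a, t) in enumerate(zip(alphas, thetas), start=1):
        logit_se = (a / 2.0 + t) * np.exp(-beta / 2.0)
        logit_sp = (a / 2.0 - t) * np.exp(beta / 2.0)
        tp = int(rng.binomial(n_diseased, expit(logit_se)))
        tn = int(rng.binomial(n_nondiseased, expit(logit_sp)))
        tables.append(
            ContingencyTable(
                study_id=i,
                threshold=np.nan,
                tp=tp,
                fn=n_diseased - tp,
                fp=n_nondiseased - tn,
                tn=tn,
            )
        )
    return tables


def load_example() -> IPDDataset:
    """The frozen synthetic example dataset shipped with the package.

    A stand-in for a hypothetical 15-study meta-analysis; fully synthetic,
    produced by :func:`generate_frame` with the default configuration.
    """
    from importlib.resources import files

    with (files("ipdmeta") / "data" / "synthetic_ipd.csv").open("rb") as fh:
        return dataio.load_ipd_csv(fh, separator="comma")
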