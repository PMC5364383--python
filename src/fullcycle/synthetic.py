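"""Synthetic full-annual-cycle demographic data.

Generates ground-truth trajectories from a two-sex, three-stage pre-breeding
projection (local recruits R, surviving adults S, immigrants I) with
demographic stochasticity, then emits the three observed data sets the
integrated model consumes: sex-specific counts, individual encounter
histories, and annual productivity records, plus annual covariates.

The simulation is individual-based: each fledgling and breeder is tracked, so
the aggregated stage counts follow the binomial/Poisson state equations
exactly *and* the capture-recapture histories refer to the same individuals
that are counted — as in the field data this emulates.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .constants import RATES, SEXES
from .io import EncounterData, write_encounters, write_table

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "default_sigma",
    "default_beta",
    "simulate_covariates",
    "simulate_population",
    "generate_observations",
    "simulate_dataset",
    "write_dataset",
]

# Stationary (mean, SD) of each simulated annual covariate, chosen to mimic
# the scale of coastal mid-Atlantic winters and Bay-of-Fundy summers; the
# winter abundance index mimics a CBC birds-per-hour series.
COVARIATE_MOMENTS = {
    "winter_temp": (10.0, 1.2),
    "winter_prcp": (2.8, 0.6),
    "prebreeding_temp": (8.0, 1.3),
    "prebreeding_prcp": (2.5, 0.7),
    "breeding_temp": (15.5, 1.0),
    "breeding_prcp": (2.7, 0.7),
    "postbreeding_temp": (14.0, 1.1),
    "postbreeding_prcp": (2.9, 0.8),
    "winter_density": (0.84, 0.15),
}


def default_sigma() -> np.ndarray:
    """Default 7x7 residual covariance on the link scale.

    SDs of 0.25 (juvenile survival, immigration), 0.2 (adult survival) and
    0.12 (fecundity) with exchangeable correlation 0.3: vital rates share
    good and bad years, as the joint-winter-conditions model implies, and the
    resulting annual growth rates span roughly 0.5-1.7.
    """
    sd = np.array([0.25, 0.25, 0.2, 0.2, 0.12, 0.25, 0.25])
    corr = np.full((7, 7), 0.3)
    np.fill_diagonal(corr, 1.0)
    return corr * np.outer(sd, sd)


def default_beta() -> dict[str, dict[str, float]]:
    """Default link-scale covariate effects: warm winters raise survival and
    immigration; high breeding density suppresses fecundity, juvenile
    survival and adult male survival (limitation vs. regulation)."""
    return {
        "phi_j_f": {"winter_temp": 0.35, "breeding_density": -0.30},
        "phi_j_m": {"winter_temp": 0.35, "breeding_density": -0.30},
        "phi_ad_f": {"winter_temp": 0.30},
        "phi_ad_m": {"winter_temp": 0.30, "breeding_density": -0.35},
        "rho": {"breeding_density": -0.25},
        "iota_f": {"winter_temp": 0.30},
        "iota_m": {"winter_temp": 0.30},
    }


@dataclass
class SimulationConfig:
    """Ground-truth configuration of the simulated study system.

    Defaults emulate the 26-year island songbird study the model targets:
    ~50-114 breeding adults, a 3-year monitoring gap at occasions 18-20,
    detection 0.93 (juveniles) / 0.96 (adults).

    Link-scale means are derived from the natural-scale fields: survival and
    detection via logit, fecundity and expected immigrants via log.
    """

    n_years: int = 26
    init_abundance: dict = dc_field(
        default_factory=lambda: {"R": (12, 12), "S": (20, 20), "I": (8, 8)}
    )
    mu_phi_j: tuple[float, float] = (0.2, 0.2)  # (f, m) probability
    mu_phi_ad: tuple[float, float] = (0.5, 0.5)
    mu_rho: float = 3.0  # fledglings per female
    mu_iota: tuple[float, float] = (8.0, 8.0)  # expected immigrants per sex
    beta: dict = dc_field(default_factory=default_beta)
    Sigma: np.ndarray = dc_field(default_factory=default_sigma)
    mu_p: dict = dc_field(default_factory=lambda: {"juv": 0.93, "ad": 0.96})
    sigma_obs: float = 0.05
    gap_years: frozenset = frozenset({18, 19, 20})
    seed: int = 0
    # Fixed reference used to standardize the (endogenous) breeding density
    # covariate inside the simulation.
    density_ref: tuple[float, float] = (80.0, 15.0)
    covariate_ar1: float = 0.0

    def validate(self) -> None:
        if self.n_years < 3:
            raise ValueError("n_years must be >= 3")
        probs = (*self.mu_phi_j, *self.mu_phi_ad, *self.mu_p.values())
        for v in probs:
            if not 0.0 <= v <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.mu_rho <= 0 or min(self.mu_iota) < 0:
            raise ValueError("fecundity must be positive, immigration non-negative")
        S = np.asarray(self.Sigma, dtype=float)
        if S.shape != (7, 7) or not np.allclose(S, S.T):
            raise ValueError("Sigma must be symmetric 7x7")
        if np.linalg.eigvalsh(S).min() < -1e-10:
            raise ValueError("Sigma must be positive semi-definite")
        if not set(self.gap_years) <= set(range(self.n_years)):
            raise ValueError("gap_years must be occasion indices")
        for r in self.beta:
            if r not in RATES:
                raise ValueError(f"unknown vital rate {r!r} in beta")


@dataclass
class TruthRecord:
    """Latent truth of one simulated replicate.

    Abundance arrays are indexed ``[sex, year]`` with sex 0=female, 1=male.
    ``phi_j``, ``phi_ad`` hold realized survival for intervals t -> t+1
    (shape (2, T-1)); ``rho`` is fecundity per year (T,); ``iota[:, t]`` is
    the expected number of immigrants *arriving* in year t (t >= 1).
    """

    R: np.ndarray
    S: np.ndarray
    I: np.ndarray
    F_tot: np.ndarray
    F_f: np.ndarray
    phi_j: np.ndarray
    phi_ad: np.ndarray
    rho: np.ndarray
    iota: np.ndarray
    eps: np.ndarray
    covariates: pd.DataFrame
    config: SimulationConfig
    individuals: list = dc_field(default_factory=list, repr=False)

    @property
    def B(self) -> np.ndarray:
        return self.R + self.S + self.I

    @property
    def lam(self) -> np.ndarray:
        tot = self.B.sum(axis=0).astype(float)
        return tot[1:] / tot[:-1]

    @property
    def omega(self) -> np.ndarray:
        tot = self.B.sum(axis=0).astype(float)
        return self.I.sum(axis=0)[1:] / tot[:-1]

    def validate(self) -> None:
        assert (self.B == self.R + self.S + self.I).all()
        assert (self.R >= 0).all() and (self.S >= 0).all() and (self.I >= 0).all()
        F_sex = np.stack([self.F_f, self.F_tot - self.F_f])
        assert (self.R[:, 1:] <= F_sex[:, :-1]).all()
        assert (self.S[:, 1:] <= self.B[:, :-1]).all()


def simulate_covariates(
    n_years: int, seed: int, ar1: float = 0.0, moments: dict | None = None
) -> pd.DataFrame:
    """Annual weather and winter-abundance covariates from stationary
    Gaussian processes (iid by default; AR(1) with coefficient ``ar1``)."""
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    if not -1.0 < ar1 < 1.0:
        raise ValueError("ar1 must lie in (-1, 1)")
    moments = COVARIATE_MOMENTS if moments is None else moments
    rng = np.random.default_rng(seed)
    out = {"year": np.arange(n_years)}
    for name, (mean, sd) in moments.items():
        z = rng.standard_normal(n_years)
        if ar1 != 0.0:
            for t in range(1, n_years):
                z[t] = ar1 * z[t - 1] + np.sqrt(1 - ar1**2) * z[t]
        out[name] = mean + sd * z
    return pd.DataFrame(out)


class _Bird:
    """One tracked individual: its presence span and marking status."""

    __slots__ = ("sex", "birth_year", "origin", "last_year", "banded_at_birth")

    def __init__(self, sex, birth_year, origin, banded_at_birth):
        self.sex = sex  # 0=f, 1=m
        self.birth_year = birth_year  # fledged (local) or arrived age 1 (immigrant)
        self.origin = origin  # 'local' | 'immigrant'
        self.last_year = birth_year  # last year alive and present
        self.banded_at_birth = banded_at_birth

    def age_at(self, t):
        # Immigrants are assumed 1-year-olds on arrival.
        base = 0 if self.origin == "local" else 1
        return base + (t - self.birth_year)


def _link_scale_mu(config: SimulationConfig) -> np.ndarray:
    with np.errstate(divide="ignore"):
        logit = lambda p: np.inf if p >= 1 else (-np.inf if p <= 0 else np.log(p / (1 - p)))
        log0 = lambda x: np.log(x) if x > 0 else -np.inf
        return np.array(
            [
                logit(config.mu_phi_j[0]),
                logit(config.mu_phi_j[1]),
                logit(config.mu_phi_ad[0]),
                logit(config.mu_phi_ad[1]),
                log0(config.mu_rho),
                log0(config.mu_iota[0]),
                log0(config.mu_iota[1]),
            ]
        )


def _detection_prob(mu_p: dict, age_class: str, sex_idx: int) -> float:
    """Detection probability for an age class ('juv'/'ad') and sex (0=f, 1=m);
    accepts either shared ('juv') or sex-specific ('juv_f') keys."""
    key = f"{age_class}_{'fm'[sex_idx]}"
    return float(mu_p.get(key, mu_p[age_class]))


def simulate_population(
    config: SimulationConfig, covariates: pd.DataFrame | None = None
) -> TruthRecord:
    """Project the two-sex three-stage population forward with demographic
    stochasticity and covariate-driven, MVN-correlated vital rates.

    Weather covariates are standardized over the simulated span before the
    link-scale effects apply; the endogenous breeding-density covariate is
    standardized by the fixed reference in the config (its value in year t is
    the realized breeder total B_t, so density dependence feeds back).
    """
    config.validate()
    T = config.n_years
    rng = np.random.default_rng(config.seed)
    if covariates is None:
        covariates = simulate_covariates(T, rng.integers(2**31), ar1=config.covariate_ar1)

    # Standardize exogenous covariates once over the study span.
    Xstd: dict[str, np.ndarray] = {}
    for name in covariates.columns:
        if name == "year":
            continue
        v = covariates[name].to_numpy(dtype=float)
        sd = v.std()
        Xstd[name] = (v - v.mean()) / sd if sd > 0 else np.zeros(T)

    mu = _link_scale_mu(config)
    eps = rng.multivariate_normal(np.zeros(7), config.Sigma, size=T, method="eigh")
    d_mean, d_sd = config.density_ref

    R = np.zeros((2, T), dtype=np.int64)
    S = np.zeros((2, T), dtype=np.int64)
    I = np.zeros((2, T), dtype=np.int64)
    F_tot = np.zeros(T, dtype=np.int64)
    F_f = np.zeros(T, dtype=np.int64)
    phi_j = np.zeros((2, T - 1))
    phi_ad = np.zeros((2, T - 1))
    rho = np.zeros(T)
    iota = np.zeros((2, T))

    birds: list[_Bird] = []
    for s in range(2):
        R[s, 0] = config.init_abundance["R"][s]
        S[s, 0] = config.init_abundance["S"][s]
        I[s, 0] = config.init_abundance["I"][s]
        for _ in range(R[s, 0]):
            birds.append(_Bird(s, -1, "local", False))
        for _ in range(S[s, 0]):
            b = _Bird(s, -2, "local", False)
            birds.append(b)
        for _ in range(I[s, 0]):
            birds.append(_Bird(s, 0, "immigrant", False))
    alive = list(birds)

    def eta(rate_idx: int, t: int, density: float) -> float:
        name = RATES[rate_idx]
        val = mu[rate_idx] + eps[t, rate_idx]
        for cov, coef in config.beta.get(name, {}).items():
            if cov == "breeding_density":
                x = (density - d_mean) / d_sd
            elif cov == "breeding_density_detrended":
                x = (density - d_mean) / d_sd
            else:
                x = Xstd[cov][t]
            val += coef * x
        return val

    from scipy.special import expit

    for t in range(T):
        B_t = R[:, t] + S[:, t] + I[:, t]
        density = float(B_t.sum())

        # Reproduction at t.
        rho[t] = np.exp(eta(4, t, density))
        F_tot[t] = rng.poisson(rho[t] * B_t[0])
        F_f[t] = rng.binomial(F_tot[t], 0.5)
        fledglings = []
        for k in range(F_tot[t]):
            sex = 0 if k < F_f[t] else 1
            b = _Bird(sex, t, "local", t not in config.gap_years)
            fledglings.append(b)
            birds.append(b)

        if t == T - 1:
            break

        # Survival t -> t+1 and immigration into t+1.
        for s in range(2):
            phi_j[s, t] = expit(eta(s, t, density))
            phi_ad[s, t] = expit(eta(2 + s, t, density))
            iota[s, t + 1] = np.exp(eta(5 + s, t, density))

        next_alive = []
        for b in alive:
            if rng.random() < phi_ad[b.sex, t]:
                b.last_year = t + 1
                next_alive.append(b)
                S[b.sex, t + 1] += 1
        for b in fledglings:
            if rng.random() < phi_j[b.sex, t]:
                b.last_year = t + 1
                next_alive.append(b)
                R[b.sex, t + 1] += 1
        for s in range(2):
            I[s, t + 1] = rng.poisson(iota[s, t + 1])
            for _ in range(I[s, t + 1]):
                b = _Bird(s, t + 1, "immigrant", False)
                birds.append(b)
                next_alive.append(b)
        alive = next_alive

    truth = TruthRecord(
        R=R, S=S, I=I, F_tot=F_tot, F_f=F_f,
        phi_j=phi_j, phi_ad=phi_ad, rho=rho, iota=iota, eps=eps,
        covariates=covariates, config=config, individuals=birds,
    )
    truth.validate()
    return truth


def generate_observations(
    truth: TruthRecord, config: SimulationConfig | None = None
) -> tuple[EncounterData, pd.DataFrame, pd.DataFrame]:
    """Observe the truth: lognormal counts, Bernoulli encounter histories,
    and Poisson productivity records.

    Monitoring is suspended in gap years: counts and productivity are missing
    (not zero), detection is structurally zero, and fledglings of gap years
    are never banded in the nest (if they recruit they are first captured
    later as adults of unknown age, like immigrants).
    """
    config = truth.config if config is None else config
    T = config.n_years
    rng = np.random.default_rng(config.seed + 1_000_003)
    B = truth.B
    gap = config.gap_years

    # Counts: lognormal around true sex-specific breeder numbers.
    C = np.full((2, T), np.nan)
    for t in range(T):
        if t in gap:
            continue
        for s in range(2):
            if B[s, t] == 0:
                C[s, t] = 0.0
            else:
                C[s, t] = np.round(np.exp(np.log(B[s, t]) + config.sigma_obs * rng.standard_normal()))
    counts = pd.DataFrame({"year": np.arange(T), "C_f": C[0], "C_m": C[1]})

    # Encounter histories.  A bird banded as a nestling has detection 1 at its
    # fledging occasion; marked birds are re-detected with the age-specific
    # probability (age 1 -> juvenile p, older -> adult p).  Immigrants and
    # gap-year local recruits are first captured as adults with the adult p.
    ids, sexes, ages, rows = [], [], [], []
    for idx, b in enumerate(truth.individuals):
        h = np.zeros(T, dtype=np.int64)
        banded = False
        age_first = None
        for t in range(max(b.birth_year, 0), b.last_year + 1):
            if t in gap or t >= T:
                continue
            age = b.age_at(t)
            if not banded and b.origin == "local" and age == 0:
                if b.banded_at_birth:
                    h[t] = 1
                    banded = True
                    age_first = "juvenile"
                continue
            if age == 0:
                continue
            if b.origin == "local" and b.banded_at_birth:
                p = _detection_prob(config.mu_p, "juv" if age == 1 else "ad", b.sex)
            else:
                p = _detection_prob(config.mu_p, "ad", b.sex)
            if rng.random() < p:
                h[t] = 1
                if not banded:
                    banded = True
                    age_first = "adult"
        if banded:
            ids.append(f"b{idx}")
            sexes.append("fm"[b.sex])
            ages.append(age_first)
            rows.append(h)
    enc = EncounterData(
        ids=np.array(ids),
        sex=np.array(sexes),
        age_first=np.array(ages),
        histories=np.array(rows, dtype=np.int64).reshape(len(rows), T),
    )

    # Productivity: fledglings from surveyed females.
    J = np.full(T, np.nan)
    females = np.full(T, np.nan)
    for t in range(T):
        if t in gap or not np.isfinite(C[0, t]):
            continue
        females[t] = C[0, t]
        J[t] = rng.poisson(truth.rho[t] * females[t])
    productivity = pd.DataFrame({"year": np.arange(T), "J": J, "females_surveyed": females})

    return enc, counts, productivity


def simulate_dataset(config: SimulationConfig | None = None):
    """One-call convenience: truth plus the three observed tables."""
    config = SimulationConfig() if config is None else config
    truth = simulate_population(config)
    enc, counts, productivity = generate_observations(truth)
    return truth, enc, counts, productivity


def write_dataset(outdir, config: SimulationConfig | None = None) -> dict:
    """Simulate and write encounters/counts/productivity/covariates/truth CSVs."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth, enc, counts, productivity = simulate_dataset(config)
    write_encounters(enc, outdir / "encounters.csv")
    write_table(counts, outdir / "counts.csv")
    write_table(productivity, outdir / "productivity.csv")
    write_table(truth.covariates, outdir / "covariates.csv")
    truth_df = pd.DataFrame({"year": np.arange(truth.config.n_years)})
    for s, lab in enumerate(SEXES):
        truth_df[f"R_{lab}"] = truth.R[s]
        truth_df[f"S_{lab}"] = truth.S[s]
        truth_df[f"I_{lab}"] = truth.I[s]
        truth_df[f"B_{lab}"] = truth.B[s]
    truth_df["F_tot"] = truth.F_tot
    truth_df["F_f"] = truth.F_f
    truth_df["rho"] = truth.rho
    for s, lab in enumerate(SEXES):
        truth_df[f"phi_j_{lab}"] = np.append(truth.phi_j[s], np.nan)
        truth_df[f"phi_ad_{lab}"] = np.append(truth.phi_ad[s], np.nan)
        truth_df[f"iota_{lab}"] = truth.iota[s]
    write_table(truth_df, outdir / "truth.csv")
    paths = {
        name: str(outdir / f"{name}.csv")
        for name in ("encounters", "counts", "productivity", "covariates", "truth")
    }
    return paths
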