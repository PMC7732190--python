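"""Substitution-model building blocks for amino-acid sequence evolution.

A site model combines
  * an exchangeability matrix (LG or Poisson/F81-style uniform),
  * a description of stationary amino-acid frequencies -- a single profile,
    a finite mixture of profiles (the C10/C60 style of site heterogeneity),
    or one fixed profile per alignment column (the PMSF representation), and
  * discrete-gamma rate variation across sites.

Rate matrices follow the general time-reversible construction
``Q_ij = s_ij * pi_j`` normalized to one expected substitution per unit
branch length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .core import AA_ORDER, Alignment
from .lg_data import lg_exchangeability_matrix, lg_frequencies

_MIN_FREQ = 1e-10


class ModelError(ValueError):
    """Invalid model specification."""


# ---------------------------------------------------------------------------
# Exchangeabilities and frequency profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExchangeabilityMatrix:
    """Symmetric non-negative relative substitution propensities."""

    values: np.ndarray
    name: str = "custom"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (20, 20):
            raise ModelError("exchangeability matrix must be 20x20")
        if not np.allclose(v, v.T):
            raise ModelError("exchangeability matrix must be symmetric")
        if (v < 0).any():
            raise ModelError("exchangeabilities must be non-negative")
        v = v.copy()
        np.fill_diagonal(v, 0.0)
        v.setflags(write=False)
        object.__setattr__(self, "values", v)

    @classmethod
    def lg(cls) -> "ExchangeabilityMatrix":
        return cls(lg_exchangeability_matrix(), name="LG")

    @classmethod
    def poisson(cls) -> "ExchangeabilityMatrix":
        m = np.ones((20, 20))
        np.fill_diagonal(m, 0.0)
        return cls(m, name="Poisson")


@dataclass(frozen=True)
class FrequencyProfile:
    """A probability distribution over the 20 amino acids."""

    probabilities: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.probabilities, dtype=float)
        if p.shape != (20,):
            raise ModelError("profile must have 20 entries")
        if (p < 0).any():
            raise ModelError("profile entries must be non-negative")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ModelError(f"profile sums to {p.sum()!r}, not 1")
        p = p.copy()
        p.setflags(write=False)
        object.__setattr__(self, "probabilities", p)

    @classmethod
    def uniform(cls) -> "FrequencyProfile":
        return cls(np.full(20, 1 / 20))

    @classmethod
    def lg(cls) -> "FrequencyProfile":
        return cls(lg_frequencies())

    @classmethod
    def from_alignment(cls, alignment: Alignment) -> "FrequencyProfile":
        """Empirical (+F) frequencies observed in an alignment."""
        return cls(alignment.state_frequencies())

    def clamped(self) -> np.ndarray:
        """Entries with zeros clamped to 1e-10, renormalized."""
        p = np.maximum(self.probabilities, _MIN_FREQ)
        return p / p.sum()


@dataclass(frozen=True)
class ProfileMixture:
    """A finite mixture of frequency profiles with simplex weights."""

    components: tuple[FrequencyProfile, ...]
    weights: np.ndarray

    def __post_init__(self):
        comps = tuple(self.components)
        if not comps:
            raise ModelError("mixture needs at least one component")
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(comps),):
            raise ModelError("one weight per component required")
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ModelError("weights must be a simplex")
        w = w / w.sum()
        w.setflags(write=False)
        object.__setattr__(self, "components", comps)
        object.__setattr__(self, "weights", w)

    @property
    def n_components(self) -> int:
        return len(self.components)

    def profile_matrix(self) -> np.ndarray:
        """(n_components, 20) matrix of component probabilities."""
        return np.vstack([c.probabilities for c in self.components])

    def reweighted(self, weights) -> "ProfileMixture":
        return ProfileMixture(self.components, np.asarray(weights, float))

    # -- TSV interchange: one row per component, weight then 20 freqs ------

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("weight\t" + "\t".join(AA_ORDER) + "\n")
            for w, comp in zip(self.weights, self.components):
                row = "\t".join(f"{x:.10g}" for x in comp.probabilities)
                fh.write(f"{w:.10g}\t{row}\n")

    @classmethod
    def read_tsv(cls, path) -> "ProfileMixture":
        rows = []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("weight"):
                raise ModelError("profile TSV must start with a header row")
            for line in fh:
                if line.strip():
                    rows.append([float(x) for x in line.split("\t")])
        if not rows:
            raise ModelError("empty profile TSV")
        arr = np.asarray(rows)
        comps = [FrequencyProfile(r / r.sum()) for r in arr[:, 1:]]
        return cls(tuple(comps), arr[:, 0] / arr[:, 0].sum())


# ---------------------------------------------------------------------------
# Discrete-gamma rate variation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GammaRates:
    """Equal-probability discrete-gamma rate categories with mean 1."""

    alpha: float
    k: int
    rates: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.rates, dtype=float)
        if r.shape != (self.k,):
            raise ModelError("rates length must equal k")
        if abs(r.mean() - 1.0) > 1e-10:
            raise ModelError("mean rate must be 1")
        if self.k > 1 and not (np.diff(r) > 0).all():
            raise ModelError("rates must be strictly increasing")
        r = r.copy()
        r.setflags(write=False)
        object.__setattr__(self, "rates", r)

    @classmethod
    def constant(cls) -> "GammaRates":
        return cls(np.inf, 1, np.ones(1))


def discrete_gamma(alpha: float, k: int = 4) -> GammaRates:
    """Discretize Gamma(alpha, alpha) into ``k`` equal-probability categories.

    Each category's rate is its conditional mean (Yang 1994), computed from
    the regularized incomplete gamma function, so the mean rate is exactly 1.
    """
    if alpha <= 0:
        raise ModelError("gamma shape must be positive")
    if k < 1:
        raise ModelError("need at least one rate category")
    if k == 1:
        return GammaRates(alpha, 1, np.ones(1))
    # category boundaries in the Gamma(alpha, scale=1/alpha) distribution
    edges = gamma_dist.ppf(np.arange(1, k) / k, a=alpha, scale=1.0 / alpha)
    upper = np.concatenate([gammainc(alpha + 1, alpha * edges), [1.0]])
    lower = np.concatenate([[0.0], gammainc(alpha + 1, alpha * edges)])
    rates = k * (upper - lower)
    rates = rates / rates.mean()  # exact mean-1 despite roundoff
    return GammaRates(alpha, k, rates)


# ---------------------------------------------------------------------------
# Rate matrices and transition probabilities
# ---------------------------------------------------------------------------


def build_rate_matrix(ex: ExchangeabilityMatrix,
                      profile: FrequencyProfile) -> np.ndarray:
    """GTR-family rate matrix ``Q_ij = s_ij pi_j``, unit expected rate.

    Rows sum to zero; the normalization makes one unit of branch length
    equal one expected substitution per site at stationarity; detailed
    balance ``pi_i Q_ij = pi_j Q_ji`` holds by construction.
    """
    pi = profile.clamped()
    q = ex.values * pi[None, :]
    np.fill_diagonal(q, 0.0)
    q[np.diag_indices(20)] = -q.sum(axis=1)
    scale = -np.dot(pi, np.diag(q))
    return q / scale


def transition_matrix(q: np.ndarray, t: float) -> np.ndarray:
    """Stochastic matrix ``P(t) = exp(Q t)`` for branch length x rate ``t``."""
    if t < 0:
        raise ModelError("branch length must be non-negative")
    if t == 0:
        return np.eye(20)
    return expm(q * t)


def spectral_decomposition(ex: ExchangeabilityMatrix,
                           profile: FrequencyProfile):
    """Eigendecomposition of a reversible Q for fast repeated P(t).

    Returns ``(lam, left, right)`` with
    ``P(t) = left @ diag(exp(lam t)) @ right``; uses the similarity
    transform ``diag(sqrt(pi)) Q diag(1/sqrt(pi))``, which is symmetric for
    reversible models, so a stable symmetric eigensolver applies.
    """
    pi = profile.clamped()
    q = build_rate_matrix(ex, profile)
    sq = np.sqrt(pi)
    sym = q * (sq[:, None] / sq[None, :])
    sym = (sym + sym.T) / 2
    lam, w = np.linalg.eigh(sym)
    left = w / sq[:, None]
    right = w.T * sq[None, :]
    return lam, left, right


# ---------------------------------------------------------------------------
# Site models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SiteModel:
    """Exchangeabilities + frequency description + gamma rates.

    ``frequency_mode`` is one of ``"single"``, ``"mixture"``, ``"per_site"``.
    In per-site mode ``site_profiles`` must hold one profile per column of
    the paired alignment.
    """

    exchangeabilities: ExchangeabilityMatrix
    gamma: GammaRates
    frequency_mode: str = "single"
    profile: FrequencyProfile | None = None
    mixture: ProfileMixture | None = None
    site_profiles: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.frequency_mode == "single":
            if self.profile is None:
                object.__setattr__(self, "profile", FrequencyProfile.lg()
                                   if self.exchangeabilities.name == "LG"
                                   else FrequencyProfile.uniform())
        elif self.frequency_mode == "mixture":
            if self.mixture is None:
                raise ModelError("mixture mode requires a ProfileMixture")
        elif self.frequency_mode == "per_site":
            if self.site_profiles is None:
                raise ModelError("per_site mode requires site_profiles")
            sp = np.asarray(self.site_profiles, dtype=float)
            if sp.ndim != 2 or sp.shape[1] != 20:
                raise ModelError("site_profiles must be (n_sites, 20)")
            if not np.allclose(sp.sum(axis=1), 1.0, atol=1e-8):
                raise ModelError("site profiles must each sum to 1")
            object.__setattr__(self, "site_profiles", sp)
        else:
            raise ModelError(f"unknown frequency_mode {self.frequency_mode!r}")

    # -- convenience constructors -----------------------------------------

    @classmethod
    def homogeneous(cls, ex: ExchangeabilityMatrix | None = None,
                    profile: FrequencyProfile | None = None,
                    alpha: float | None = 1.0, k: int = 4) -> "SiteModel":
        """Single-profile model; LG+G with LG frequencies by default."""
        ex = ex or ExchangeabilityMatrix.lg()
        gamma = GammaRates.constant() if alpha is None else discrete_gamma(alpha, k)
        return cls(ex, gamma, "single", profile=profile)

    @classmethod
    def lg_g(cls, alpha: float = 1.0, k: int = 4,
             empirical_from: Alignment | None = None) -> "SiteModel":
        """LG+G; pass ``empirical_from`` for observed (+F) frequencies."""
        profile = (FrequencyProfile.from_alignment(empirical_from)
                   if empirical_from is not None else None)
        return cls.homogeneous(ExchangeabilityMatrix.lg(), profile, alpha, k)

    @classmethod
    def mixture_model(cls, mixture: ProfileMixture,
                      ex: ExchangeabilityMatrix | None = None,
                      alpha: float | None = 1.0, k: int = 4) -> "SiteModel":
        ex = ex or ExchangeabilityMatrix.lg()
        gamma = GammaRates.constant() if alpha is None else discrete_gamma(alpha, k)
        if mixture.n_components == 1:
            return cls(ex, gamma, "single", profile=mixture.components[0])
        return cls(ex, gamma, "mixture", mixture=mixture)

    @classmethod
    def cat_f81(cls, mixture: ProfileMixture,
                alpha: float | None = 1.0, k: int = 4) -> "SiteModel":
        """Profile mixture over Poisson exchangeabilities (CAT-F81 analog)."""
        return cls.mixture_model(mixture, ExchangeabilityMatrix.poisson(),
                                 alpha, k)

    @classmethod
    def per_site(cls, site_profiles: np.ndarray,
                 ex: ExchangeabilityMatrix | None = None,
                 alpha: float | None = 1.0, k: int = 4) -> "SiteModel":
        ex = ex or ExchangeabilityMatrix.lg()
        gamma = GammaRates.constant() if alpha is None else discrete_gamma(alpha, k)
        return cls(ex, gamma, "per_site", site_profiles=site_profiles)

    # -- derived views -----------------------------------------------------

    def component_profiles(self) -> np.ndarray:
        """(n_components, 20) stationary profiles (per-site mode: per site)."""
        if self.frequency_mode == "single":
            return self.profile.probabilities[None, :]
        if self.frequency_mode == "mixture":
            return self.mixture.profile_matrix()
        return self.site_profiles

    def component_weights(self) -> np.ndarray:
        if self.frequency_mode == "mixture":
            return np.asarray(self.mixture.weights)
        return np.ones(1)

    def with_alpha(self, alpha: float) -> "SiteModel":
        gamma = discrete_gamma(alpha, self.gamma.k)
        return SiteModel(self.exchangeabilities, gamma, self.frequency_mode,
                         profile=self.profile, mixture=self.mixture,
                         site_profiles=self.site_profiles)

    def describe(self) -> str:
        ex = self.exchangeabilities.name
        g = f"+G({self.gamma.alpha:g},k={self.gamma.k})" if self.gamma.k > 1 else ""
        if self.frequency_mode == "single":
            return f"{ex}{g}"
        if self.frequency_mode == "mixture":
            return f"{ex}+C{self.mixture.n_components}{g}"
        return f"{ex}+PMSF{g}"
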