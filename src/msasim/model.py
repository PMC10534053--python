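"""Nucleotide substitution models and among-site rate heterogeneity.

The substitution process is a reversible continuous-time Markov chain on the
four nucleotide states.  A general time reversible (GTR) model is assembled
from six symmetric exchangeability multipliers ``s_ij`` and a stationary
distribution ``pi``:

    Q_ij = s_ij * pi_j            (i != j)
    Q_ii = -sum_{j != i} Q_ij

The matrix is then globally rescaled so that ``-sum_i pi_i Q_ii = 1``, i.e.
branch lengths are measured in expected substitutions per site.

Rate variation across sites combines a proportion ``p_inv`` of invariant
(rate-0) sites with a k-category discretization of a Gamma(alpha) distribution
of mean 1 (equal-probability bins, category rate = bin mean).  Non-invariant
rates are rescaled by ``1/(1 - p_inv)`` so the expected rate over all sites
stays 1 and branch lengths keep their per-site meaning.
"""

from __future__ import annotations

import re

import numpy as np
from scipy.special import gammainc, gammaincinv

__all__ = [
    "DNA_STATES",
    "EXCHANGEABILITY_ORDER",
    "ModelError",
    "SubstitutionModel",
    "SiteRateModel",
    "build_model",
    "jukes_cantor",
    "transition_matrix",
    "discrete_gamma_rates",
    "assign_site_rates",
    "parse_model_spec",
]

#: Fixed state order for DNA; pinned for reproducibility.
DNA_STATES = ("A", "C", "G", "T")

#: Fixed order of the six exchangeability parameters.
EXCHANGEABILITY_ORDER = ("AC", "AG", "AT", "CG", "CT", "GT")


class ModelError(ValueError):
    """Invalid substitution- or rate-model parameters."""


def _as_generator(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


class SubstitutionModel:
    """Normalized reversible rate matrix with cached spectral decomposition.

    Parameters
    ----------
    exchangeabilities:
        Six positive multipliers in the order AC, AG, AT, CG, CT, GT.
    frequencies:
        Four positive stationary frequencies summing to 1 (renormalized;
        a deviation above 1e-3 is rejected).
    """

    def __init__(self, exchangeabilities, frequencies):
        s = np.asarray(exchangeabilities, dtype=float)
        pi = np.asarray(frequencies, dtype=float)
        if s.shape != (6,):
            raise ModelError(f"expected 6 exchangeabilities, got shape {s.shape}")
        if pi.shape != (4,):
            raise ModelError(f"expected 4 frequencies, got shape {pi.shape}")
        if not np.all(s > 0):
            raise ModelError("exchangeabilities must be strictly positive")
        if not np.all(pi > 0):
            raise ModelError("frequencies must be strictly positive")
        if abs(pi.sum() - 1.0) > 1e-3:
            raise ModelError(f"frequencies sum to {pi.sum():.6f}, expected 1")
        pi = pi / pi.sum()

        S = np.zeros((4, 4))
        idx = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        for (i, j), v in zip(idx, s):
            S[i, j] = S[j, i] = v
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -float(np.dot(pi, np.diag(Q)))  # expected rate before scaling
        Q /= mu

        self.alphabet = DNA_STATES
        self.exchangeabilities = s
        self.frequencies = pi
        self.rate_matrix = Q

        # pi^{1/2} similarity transform makes Q symmetric: real spectrum,
        # orthogonal eigenvectors, stable matrix exponential.
        sq = np.sqrt(pi)
        A = (Q * sq[:, None]) / sq[None, :]
        A = 0.5 * (A + A.T)
        w, V = np.linalg.eigh(A)
        self._eigenvalues = w
        self._right = V / sq[:, None]          # diag(1/sqrt(pi)) @ V
        self._left = V.T * sq[None, :]         # V.T @ diag(sqrt(pi))
        self._state_bytes = np.frombuffer(
            "".join(self.alphabet).encode("ascii"), dtype=np.uint8
        )

    # -- transition probabilities -------------------------------------------------

    def transition_matrix(self, t: float) -> np.ndarray:
        """``P(t) = exp(Q t)``; row-stochastic, entries clamped to [0, 1]."""
        if t < 0:
            raise ModelError(f"negative branch length * rate: {t}")
        if t == 0.0:
            return np.eye(4)
        P = (self._right * np.exp(self._eigenvalues * t)[None, :]) @ self._left
        np.clip(P, 0.0, 1.0, out=P)
        rows = P.sum(axis=1)
        drift = np.max(np.abs(rows - 1.0))
        if drift >= 1e-9:
            raise FloatingPointError(f"transition matrix row drift {drift:g}")
        P /= rows[:, None]
        return P

    def cumulative_rows(self, t: float) -> np.ndarray:
        """First three cumulative sums of each row of P(t).

        A uniform draw ``u`` maps to the child state ``(u >= cum).sum()``,
        which copies the parent state exactly when P(t) is the identity
        (u = 0.0 included).
        """
        return np.cumsum(self.transition_matrix(t), axis=1)[:, :3]

    def decode(self, states: np.ndarray) -> bytes:
        """Integer state codes -> ASCII sequence bytes."""
        return self._state_bytes[states].tobytes()

    def __repr__(self):  # pragma: no cover
        return (
            f"SubstitutionModel(exchangeabilities={self.exchangeabilities.tolist()}, "
            f"frequencies={self.frequencies.tolist()})"
        )


def build_model(exchangeabilities, frequencies) -> SubstitutionModel:
    """Construct a normalized GTR model (see :class:`SubstitutionModel`)."""
    return SubstitutionModel(exchangeabilities, frequencies)


def jukes_cantor() -> SubstitutionModel:
    """Equal exchangeabilities and frequencies (the JC69 special case)."""
    return SubstitutionModel(np.ones(6), np.full(4, 0.25))


def transition_matrix(model: SubstitutionModel, t: float) -> np.ndarray:
    return model.transition_matrix(t)


def discrete_gamma_rates(alpha: float, k: int):
    """Mean-of-bin discretization of Gamma(alpha) with mean 1.

    The Gamma is cut into ``k`` equal-probability bins; each category rate is
    the conditional mean of its bin, so the weighted mean rate is exactly 1
    (up to floating point).  Returns ``(rates, weights)`` with weights all
    ``1/k`` and rates in increasing order.
    """
    if alpha <= 0:
        raise ModelError(f"gamma shape must be > 0, got {alpha}")
    if int(k) != k or k < 1:
        raise ModelError(f"number of categories must be an integer >= 1, got {k}")
    k = int(k)
    if k == 1:
        return np.array([1.0]), np.array([1.0])
    # Internal bin boundaries of Gamma(alpha, scale=1); the bin mean in
    # mean-1 scale is k * [F_{alpha+1}(b_{i+1}) - F_{alpha+1}(b_i)].
    bounds = gammaincinv(alpha, np.arange(1, k) / k)
    cdf_hi = np.concatenate([gammainc(alpha + 1.0, bounds), [1.0]])
    cdf_lo = np.concatenate([[0.0], cdf_hi[:-1]])
    rates = k * (cdf_hi - cdf_lo)
    weights = np.full(k, 1.0 / k)
    rates = rates / float(rates @ weights)  # exact mean-1 guard
    return rates, weights


class SiteRateModel:
    """+I+Gamma mixture of per-site rate multipliers.

    ``p_inv`` of the sites are invariant (rate 0); the rest draw one of the
    ``n_categories`` discrete Gamma rates, rescaled by ``1/(1-p_inv)`` so the
    mixture mean is 1.  ``gamma_shape=None`` means no Gamma heterogeneity
    (a single rate class).
    """

    def __init__(self, p_inv: float = 0.0, gamma_shape: float | None = None,
                 n_categories: int = 4):
        if not 0.0 <= p_inv < 1.0:
            raise ModelError(f"p_inv must be in [0, 1), got {p_inv}")
        if gamma_shape is None:
            rates = np.array([1.0])
            weights = np.array([1.0])
            n_categories = 1
        else:
            rates, weights = discrete_gamma_rates(gamma_shape, n_categories)
        self.p_inv = float(p_inv)
        self.gamma_shape = gamma_shape
        self.n_categories = int(n_categories)
        self.category_rates = rates
        self.category_weights = weights
        if p_inv > 0.0:
            self.mixture_rates = np.concatenate([[0.0], rates / (1.0 - p_inv)])
            self.mixture_weights = np.concatenate([[p_inv], (1.0 - p_inv) * weights])
        else:
            self.mixture_rates = rates
            self.mixture_weights = weights
        mean = float(self.mixture_rates @ self.mixture_weights)
        if abs(mean - 1.0) > 1e-10:
            raise ModelError(f"mixture mean rate {mean!r} != 1")
        self._cdf = np.cumsum(self.mixture_weights)

    def draw_categories(self, L: int, rng) -> np.ndarray:
        """One mixture-category index per site (invariant class first)."""
        if L < 1:
            raise ModelError(f"sequence length must be >= 1, got {L}")
        u = _as_generator(rng).random(L)
        idx = np.searchsorted(self._cdf, u, side="right")
        return np.minimum(idx, len(self.mixture_rates) - 1).astype(np.int64)

    def __repr__(self):  # pragma: no cover
        return (
            f"SiteRateModel(p_inv={self.p_inv}, gamma_shape={self.gamma_shape}, "
            f"n_categories={self.n_categories})"
        )


def assign_site_rates(site_rate_model: SiteRateModel, L: int, rng) -> np.ndarray:
    """Per-site rate multipliers (length ``L``), expected value 1."""
    idx = site_rate_model.draw_categories(L, rng)
    return site_rate_model.mixture_rates[idx]


_COMPONENT_RE = re.compile(r"([A-Za-z]+)((?:\{[^{}]*\})*)")


def _split_braces(args: str) -> list[str]:
    return re.findall(r"\{([^{}]*)\}", args)


def parse_model_spec(spec: str) -> tuple[SubstitutionModel, SiteRateModel]:
    """Parse a model string like ``GTR{1,2,1,1,2,1}+F{.1,.2,.3,.4}+I{0.2}+G{4}{0.5}``.

    Defaults: equal exchangeabilities, equal frequencies, ``p_inv = 0``,
    ``k = 4`` when +G is present with a single argument (the shape).
    ``JC`` is an alias for the equal-everything model.
    """
    exch = np.ones(6)
    freqs = np.full(4, 0.25)
    p_inv = 0.0
    gamma_shape = None
    n_cat = 4
    seen_base = False
    for part in spec.strip().split("+"):
        part = part.strip()
        if not part:
            raise ModelError(f"empty component in model spec {spec!r}")
        m = _COMPONENT_RE.fullmatch(part)
        if not m:
            raise ModelError(f"cannot parse model component {part!r}")
        name, raw = m.group(1).upper(), _split_braces(m.group(2))
        if name in ("GTR", "JC"):
            seen_base = True
            if name == "JC" and raw:
                raise ModelError("JC takes no parameters")
            if raw:
                vals = [float(x) for x in raw[0].split(",")]
                if len(vals) != 6:
                    raise ModelError(f"GTR needs 6 exchangeabilities, got {len(vals)}")
                exch = np.asarray(vals)
        elif name == "F":
            vals = [float(x) for x in raw[0].split(",")] if raw else []
            if len(vals) != 4:
                raise ModelError(f"+F needs 4 frequencies, got {len(vals)}")
            freqs = np.asarray(vals)
        elif name == "I":
            if len(raw) != 1:
                raise ModelError("+I takes one parameter, the invariant proportion")
            p_inv = float(raw[0])
        elif name == "G":
            if len(raw) == 1:
                gamma_shape = float(raw[0])
            elif len(raw) == 2:
                n_cat = int(raw[0])
                gamma_shape = float(raw[1])
            else:
                raise ModelError("+G takes {alpha} or {k}{alpha}")
        else:
            raise ModelError(f"unknown model component {name!r}")
    if not seen_base:
        raise ModelError(f"model spec {spec!r} lacks a base model (GTR or JC)")
    return build_model(exch, freqs), SiteRateModel(p_inv, gamma_shape, n_cat)
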