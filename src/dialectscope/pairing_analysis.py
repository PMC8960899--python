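"""Pair-bond calling from dyadic interaction counts and assortment tests.

Background counts follow a zero-truncated Poisson (ZTP); the bond cutoff is
the smallest count whose observed tail frequency exceeds the ZTP-expected
tail by a fixed ratio, with an override path for a fixed protocol cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats


@dataclass
class ZTPFit:
    lambda_hat: float
    log_likelihood: float
    n: int

    def pmf(self, k: np.ndarray | int) -> np.ndarray:
        lam = self.lambda_hat
        return stats.poisson.pmf(k, lam) / (1.0 - np.exp(-lam))

    def sf_inclusive(self, k: int) -> float:
        """P(X >= k) under the fitted ZTP."""
        lam = self.lambda_hat
        return float(stats.poisson.sf(k - 1, lam) / (1.0 - np.exp(-lam)))

    @property
    def mean(self) -> float:
        lam = self.lambda_hat
        return lam / (1.0 - np.exp(-lam))


@dataclass
class PairBondSet:
    pairs: list[tuple[str, str, int]]  # (female_id, male_id, count)
    cutoff_used: int
    unpaired: list[str] = field(default_factory=list)
    multiplicity: dict[str, dict[int, int]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pairs)

    def as_tuples(self) -> list[tuple[str, str]]:
        return [(f, m) for f, m, _ in self.pairs]


@dataclass
class AssortmentSummary:
    n_pairs: int
    n_assortative: int
    proportion: float
    percentage_rounded: int
    binomial_p_two_tailed: float
    attribute: str


def fit_ztp(counts: np.ndarray | list[int]) -> ZTPFit:
    """Maximum-likelihood zero-truncated Poisson fit.

    The MLE solves m = lambda / (1 - exp(-lambda)) for the sample mean m,
    by bracketed root finding.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size < 5:
        raise ValueError("need at least 5 counts")
    if np.any(counts < 1):
        raise ValueError("zero-truncated counts must all be >= 1")
    m = counts.mean()
    if m <= 1.0 + 1e-9:
        warnings.warn("sample mean <= 1: lambda at the zero boundary", stacklevel=2)
        lam = 1e-8
    else:
        lam = optimize.brentq(lambda x: x / (1.0 - np.exp(-x)) - m, 1e-10, max(10 * m, 1.0))
    ll = float(
        np.sum(counts * np.log(max(lam, 1e-300)) - lam - special.gammaln(counts + 1))
        - counts.size * np.log1p(-np.exp(-lam))
    )
    return ZTPFit(lambda_hat=float(lam), log_likelihood=ll, n=int(counts.size))


def expected_frequencies(fit: ZTPFit, max_count: int) -> pd.DataFrame:
    """Expected ZTP frequencies for count values 1..max_count."""
    k = np.arange(1, max_count + 1)
    return pd.DataFrame({"count": k, "expected": fit.n * fit.pmf(k)})


def choose_cutoff(
    counts: np.ndarray | list[int],
    fit: ZTPFit,
    ratio_threshold: float = 5.0,
    override: int | None = None,
) -> int | None:
    """Smallest count whose observed tail frequency is at least
    ``ratio_threshold`` times the ZTP-expected tail frequency.

    A bonded component inflates a whole-sample fit, so the background fit is
    re-estimated on counts below the current cutoff until the cutoff is
    stable (fixed-point iteration starting from ``fit``).  ``override``
    bypasses the rule (fixed protocol cutoff).  Returns None when no count
    deviates (data look like a single ZTP component).
    """
    if override is not None:
        return int(override)
    counts = np.asarray(counts, dtype=int)

    def _first_deviation(f: ZTPFit) -> int | None:
        for c in range(2, int(counts.max()) + 1):
            obs_tail = int((counts >= c).sum())
            exp_tail = f.n * f.sf_inclusive(c)
            if obs_tail > 0 and obs_tail >= ratio_threshold * exp_tail:
                return c
        return None

    cutoff = _first_deviation(fit)
    for _ in range(10):
        if cutoff is None:
            return None
        background = counts[counts < cutoff]
        if background.size < 5 or background.mean() <= 1.0 + 1e-9:
            return cutoff
        refit = fit_ztp(background)
        refit = ZTPFit(refit.lambda_hat, refit.log_likelihood, n=counts.size)
        new = _first_deviation(refit)
        if new == cutoff:
            return cutoff
        cutoff = new
    return cutoff


def call_pairs(
    counts: pd.DataFrame,
    cutoff: int,
    all_birds: list[str] | None = None,
) -> PairBondSet:
    """Bond every dyad whose count reaches the cutoff.

    ``counts`` has columns (female_id, male_id, count).  Reports per-sex
    bond-multiplicity histograms and, when ``all_birds`` is given, the list
    of unpaired birds.
    """
    if cutoff < 1:
        raise ValueError("cutoff must be >= 1")
    sel = counts[counts["count"] >= cutoff]
    pairs = [
        (str(r.female_id), str(r.male_id), int(r.count)) for r in sel.itertuples(index=False)
    ]
    f_mult: dict[str, int] = {}
    m_mult: dict[str, int] = {}
    for f, m, _ in pairs:
        f_mult[f] = f_mult.get(f, 0) + 1
        m_mult[m] = m_mult.get(m, 0) + 1
    hist = {
        "F": dict(sorted(pd.Series(list(f_mult.values())).value_counts().items()))
        if f_mult
        else {},
        "M": dict(sorted(pd.Series(list(m_mult.values())).value_counts().items()))
        if m_mult
        else {},
    }
    unpaired = []
    if all_birds is not None:
        bonded = set(f_mult) | set(m_mult)
        unpaired = sorted(set(all_birds) - bonded)
    return PairBondSet(pairs=pairs, cutoff_used=int(cutoff), unpaired=unpaired,
                       multiplicity=hist)


def binomial_two_tailed(k: int, n: int, p0: float = 0.5) -> float:
    """Exact two-tailed binomial p (minimum-likelihood method; equals the
    doubled smaller tail, capped at 1, when p0 = 0.5)."""
    return float(stats.binomtest(k, n, p0, alternative="two-sided").pvalue)


def assortment_test(
    pairs: PairBondSet | list[tuple[str, str]],
    attribute_of: dict[str, str],
    *,
    attribute: str = "rearing_pop",
    null_prob: float = 0.5,
) -> AssortmentSummary:
    """Proportion of pairs whose members share the attribute level, with an
    exact two-tailed binomial test against ``null_prob``."""
    tuples = pairs.as_tuples() if isinstance(pairs, PairBondSet) else list(pairs)
    if not tuples:
        raise ValueError("no pairs to test")
    try:
        hits = sum(attribute_of[f] == attribute_of[m] for f, m in tuples)
    except KeyError as err:
        raise ValueError(f"pair member {err} has no attribute value") from err
    n = len(tuples)
    prop = hits / n
    return AssortmentSummary(
        n_pairs=n,
        n_assortative=hits,
        proportion=prop,
        percentage_rounded=int(round(100 * prop)),
        binomial_p_two_tailed=binomial_two_tailed(hits, n, null_prob),
        attribute=attribute,
    )
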