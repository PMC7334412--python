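"""Per-channel positive/negative cutoff estimation.

Manual gates are replaced by an algorithmic rule: a two-component Gaussian
mixture is fitted to the arcsinh-transformed intensities and the cutoff is
placed at the equal-posterior boundary between the two components.  When the
fit does not support a bimodal reading (component separation below 2 pooled
standard deviations, or a component carrying less than 2% of events), the
rule falls back to a quantile: the 99.5th percentile of declared
negative-control events when available, otherwise the global 95th
percentile.  The provenance (``mixture`` vs ``quantile_fallback``) is kept in
the model for every channel.

CD56 additionally gets an upper (dim/bright) boundary at the positive
component mean plus two of its standard deviations, yielding the three
regions neg / dim / bright.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm
from sklearn.mixture import GaussianMixture

from .errors import ConfigurationError, DegenerateDataError, InsufficientDataError
from .events import EventTable
from .panel import CD56, DEFAULT_COFACTOR, FLUORESCENCE

MIN_VALUES = 20
MIN_SEPARATION = 2.0
MIN_WEIGHT = 0.02
NEGATIVE_CONTROL_QUANTILE = 99.5
GLOBAL_QUANTILE = 95.0
#: events subsampled (deterministically) before the mixture fit
FIT_SUBSAMPLE = 25_000

MIXTURE = "mixture"
QUANTILE_FALLBACK = "quantile_fallback"


@dataclass(frozen=True)
class Threshold:
    """One channel's cutoff on the transformed scale, with fit provenance."""

    cutoff: float
    method: str  # "mixture" | "quantile_fallback"
    component_means: tuple[float, float] | None = None
    separation: float | None = None
    upper_cutoff: float | None = None  # dim/bright boundary (CD56 only)


@dataclass
class ThresholdModel:
    """Cutoffs for every fluorescence channel of a donor."""

    thresholds: dict[str, Threshold] = field(default_factory=dict)
    cofactor: float = DEFAULT_COFACTOR

    def cutoff(self, marker: str) -> float:
        return self[marker].cutoff

    def __getitem__(self, marker: str) -> Threshold:
        try:
            return self.thresholds[marker]
        except KeyError:
            raise ConfigurationError(f"no threshold estimated for marker {marker!r}") from None

    def __contains__(self, marker: str) -> bool:
        return marker in self.thresholds


def _equal_posterior_cutoff(means, sds, weights) -> float | None:
    """x between the means where the two weighted component densities are equal."""
    (m1, m2), (s1, s2), (w1, w2) = means, sds, weights

    def diff(x):
        return w1 * norm.pdf(x, m1, s1) - w2 * norm.pdf(x, m2, s2)

    lo, hi = m1 + 1e-9, m2 - 1e-9
    if hi <= lo or diff(lo) * diff(hi) >= 0:
        return None
    return float(brentq(diff, lo, hi, xtol=1e-10))


def estimate_threshold(values,
                       *,
                       negative_control=None,
                       with_upper: bool = False,
                       random_state: int = 0) -> Threshold:
    """Estimate a cutoff from transformed intensities of one channel.

    Parameters
    ----------
    values
        Transformed intensities (recommended n >= 200).
    negative_control
        Optional transformed intensities of declared negative-control events;
        used for the fallback quantile rule.
    with_upper
        Also derive the dim/bright upper boundary (used for CD56).
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < MIN_VALUES:
        raise InsufficientDataError(f"need at least {MIN_VALUES} values, got {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateDataError("all values identical; cannot place a cutoff")

    fit_x = x
    if fit_x.size > FIT_SUBSAMPLE:
        # deterministic thinning keeps the estimator reproducible on big tables
        rng = np.random.default_rng(random_state)
        fit_x = rng.choice(fit_x, size=FIT_SUBSAMPLE, replace=False)

    gm = GaussianMixture(n_components=2, random_state=random_state).fit(fit_x[:, None])
    order = np.argsort(gm.means_.ravel())
    means = gm.means_.ravel()[order]
    sds = np.sqrt(gm.covariances_.ravel()[order])
    weights = gm.weights_.ravel()[order]
    separation = float(abs(means[1] - means[0]) / np.sqrt((sds[0] ** 2 + sds[1] ** 2) / 2))

    cutoff = None
    if separation >= MIN_SEPARATION and weights.min() >= MIN_WEIGHT:
        cutoff = _equal_posterior_cutoff(means, sds, weights)

    if cutoff is None:
        if negative_control is not None and len(negative_control) >= MIN_VALUES:
            cut = float(np.percentile(np.asarray(negative_control, float),
                                      NEGATIVE_CONTROL_QUANTILE))
        else:
            cut = float(np.percentile(x, GLOBAL_QUANTILE))
        return Threshold(cut, QUANTILE_FALLBACK,
                         component_means=(float(means[0]), float(means[1])),
                         separation=separation,
                         upper_cutoff=(cut + 2.0) if with_upper else None)

    upper = float(means[1] + 2 * sds[1]) if with_upper else None
    return Threshold(float(cutoff), MIXTURE,
                     component_means=(float(means[0]), float(means[1])),
                     separation=separation, upper_cutoff=upper)


def estimate_table_thresholds(table: EventTable,
                              cofactor: float = DEFAULT_COFACTOR,
                              random_state: int = 0) -> ThresholdModel:
    """Fit thresholds for every fluorescence channel of an event table."""
    model = ThresholdModel(cofactor=cofactor)
    for ch in table.panel:
        if ch.role != FLUORESCENCE:
            continue
        values = table.transformed(ch.marker, cofactor)
        model.thresholds[ch.marker] = estimate_threshold(
            values, with_upper=(ch.marker == CD56), random_state=random_state)
    return model
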