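"""Constrained kernel-density mixture models for biomarker events.

Each biomarker "event" is the transition from a normal (pre-event) to an
abnormal (post-event) distribution.  Both component densities are Gaussian
kernel density estimates rather than parametric fits, which copes naturally
with the ceiling/floor pile-ups of clinical scores.  The defining constraint
is on control labelling: a control observation may carry post-event weight
only if it exceeds the pooled (controls + patients) q-quantile of the
marker — by default the 90th percentile.  Everything below stays labelled
normal, anchoring the pre-event component to the control distribution and
making the mixture read as disease-specific deviation from normality.

Fitting alternates between weighted KDEs and responsibility updates:

1. initialise responsibilities r: forced-pre observations r = 0, free
   observations (patients and above-threshold controls) r = 1;
2. fit Gaussian-kernel weighted KDEs: f_post on weights r; f_pre on weights
   (1 - r) restricted to controls, anchoring the normal component on the
   constraint-labelled control distribution.  Bandwidths follow Silverman's
   rule on each component's initial effective sample and are then held
   fixed across iterations;
3. update r_i = theta * f_post(x_i) / (theta * f_post(x_i) + (1 - theta) *
   f_pre(x_i)) for free observations, clamp forced-pre to 0, and set
   theta = mean(r);
4. repeat until max |delta r| < tol or the iteration cap.

Two numerical choices stabilise the alternation.  Anchoring f_pre on
controls stops the normal component from absorbing the abnormal mode, and
freezing the bandwidths removes the feedback loop in which a shrinking
component gets an ever wider bandwidth, a flatter density, and even less
responsibility.  When the data cannot sustain a second component the
post-event weight still collapses — deliberately so: that collapse is the
primary "no disease signal" detector.  Fixed bandwidths also let the kernel
matrix be precomputed once, so each iteration is a pair of mat-vecs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

#: Density floor keeping log-likelihoods finite.
DENSITY_FLOOR = 1e-12

_SQRT_2PI = np.sqrt(2.0 * np.pi)


@dataclass
class LabelConstraint:
    """Pooled-percentile labelling constraint for one marker.

    ``forced_pre[i]`` is True for control observations at or below the pooled
    q-quantile: these may never carry post-event responsibility.  Patients
    and above-threshold controls are free.
    """

    q: float
    threshold: float
    forced_pre: np.ndarray  # bool, aligned with the input values

    @property
    def free(self) -> np.ndarray:
        return ~self.forced_pre


def pooled_percentile_labels(
    values: np.ndarray, control_mask: np.ndarray, q: float = 0.90
) -> LabelConstraint:
    """Label controls at or below the pooled q-quantile as forced pre-event.

    ``values`` must already be oriented (larger = more abnormal).  The
    threshold is the linear-interpolation quantile of ALL non-missing values,
    controls and patients pooled.  Ties with the threshold stay forced-pre.
    """
    values = np.asarray(values, dtype=float)
    control_mask = np.asarray(control_mask, dtype=bool)
    finite = np.isfinite(values)
    if finite.sum() < 5:
        raise ValidationError("need at least 5 non-missing values for labelling")
    threshold = float(np.quantile(values[finite], q))
    forced = control_mask & ~(values > threshold) & finite
    return LabelConstraint(q=q, threshold=threshold, forced_pre=forced)


class GaussianKDE1D:
    """Weighted 1-D Gaussian KDE with a fixed bandwidth.

    density(y) = sum_i w_i * phi((y - x_i) / h) / h, with w normalised.
    """

    def __init__(self, x: np.ndarray, weights: np.ndarray, bandwidth: float):
        self.x = np.asarray(x, dtype=float)
        w = np.asarray(weights, dtype=float)
        self.weights = w / w.sum()
        self.bandwidth = float(bandwidth)

    def __call__(self, y) -> np.ndarray:
        y = np.atleast_1d(np.asarray(y, dtype=float))
        z = (y[:, None] - self.x[None, :]) / self.bandwidth
        return (np.exp(-0.5 * z * z) / (self.bandwidth * _SQRT_2PI)) @ self.weights


class _PointMassDensity:
    """Near-degenerate density for constant data where a KDE is singular."""

    def __init__(self, loc: float, scale: float = 1e-6):
        self.loc, self.scale = float(loc), float(scale)

    def __call__(self, y) -> np.ndarray:
        y = np.atleast_1d(np.asarray(y, dtype=float))
        z = (y - self.loc) / self.scale
        return np.exp(-0.5 * z * z) / (self.scale * _SQRT_2PI)


def silverman_bandwidth(x: np.ndarray, weights: np.ndarray, rule: str = "silverman") -> float:
    """Bandwidth for a weighted 1-D sample, on the effective sample size.

    neff = 1 / sum(w_tilde^2); Silverman factor (0.75 * neff)^(-1/5), Scott
    factor neff^(-1/5); bandwidth = factor * weighted SD.  Returns 0 for a
    degenerate (zero-spread) sample.
    """
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    neff = 1.0 / float(np.sum(w**2))
    mu = float(np.sum(w * x))
    var = float(np.sum(w * (x - mu) ** 2)) / max(1.0 - float(np.sum(w**2)), 1e-12)
    if var <= 0:
        return 0.0
    if rule == "scott":
        factor = neff ** (-0.2)
    else:
        factor = (0.75 * neff) ** (-0.2)
    return factor * np.sqrt(var)


def _make_kde(x: np.ndarray, weights: np.ndarray, bandwidth: float):
    if bandwidth <= 0:
        return _PointMassDensity(float(np.average(x, weights=weights)))
    return GaussianKDE1D(x, weights, bandwidth)


def _kernel_matrix(x: np.ndarray, bandwidth: float) -> np.ndarray:
    z = (x[:, None] - x[None, :]) / bandwidth
    return np.exp(-0.5 * z * z) / (bandwidth * _SQRT_2PI)


@dataclass
class EventDistribution:
    """Fitted pre/post-event densities for one marker.

    ``theta`` is the post-event mixture weight over the pooled fitting
    sample.  ``fallback`` marks degenerate fits collapsed to a single
    (pre-event) component.  Responsibilities, the constraint and the fitting
    values are retained for diagnostics and the disease-signal rule.
    """

    marker: str
    f_pre: object
    f_post: object | None
    theta: float
    orientation: int = 1
    converged: bool = False
    fallback: bool = False
    n_iterations: int = 0
    log_likelihood: float = np.nan
    values: np.ndarray = field(default=None, repr=False)
    control_mask: np.ndarray = field(default=None, repr=False)
    responsibilities: np.ndarray = field(default=None, repr=False)
    constraint: LabelConstraint | None = field(default=None, repr=False)


def _floor(d: np.ndarray) -> np.ndarray:
    return np.maximum(d, DENSITY_FLOOR)


def fit_constrained_kde_mixture(
    values: np.ndarray,
    control_mask: np.ndarray,
    constraint: LabelConstraint,
    *,
    marker: str = "",
    max_iterations: int = 100,
    tolerance: float = 1e-4,
    bandwidth_rule: str = "silverman",
) -> EventDistribution:
    """Fit the two-component constrained KDE mixture for one marker.

    Missing values are dropped before fitting (``values`` and masks must be
    aligned with the constraint).  Falls back to a single pre-event component
    (theta = 0) when either component's effective weight drops below two
    observations or the data are degenerate.
    """
    values = np.asarray(values, dtype=float)
    control_mask = np.asarray(control_mask, dtype=bool)
    finite = np.isfinite(values)
    x = values[finite]
    ctl = control_mask[finite].astype(float)
    forced = constraint.forced_pre[finite]

    r = np.where(~forced, 1.0, 0.0)

    def _fallback(n_it: int) -> EventDistribution:
        if np.ptp(x) > 0:
            bw = silverman_bandwidth(x, np.ones_like(x), bandwidth_rule)
            f_pre = _make_kde(x, np.ones_like(x), bw)
        else:
            f_pre = _PointMassDensity(float(x[0]))
        return EventDistribution(
            marker=marker, f_pre=f_pre, f_post=None, theta=0.0,
            converged=False, fallback=True, n_iterations=n_it,
            values=x, control_mask=ctl.astype(bool),
            responsibilities=np.zeros_like(x), constraint=constraint,
        )

    if np.ptp(x) == 0:
        return _fallback(0)

    w_pre0 = (1.0 - r) * ctl
    if w_pre0.sum() < 2.0 or r.sum() < 2.0:
        return _fallback(0)
    bw_pre = silverman_bandwidth(x, w_pre0, bandwidth_rule)
    bw_post = silverman_bandwidth(x, r, bandwidth_rule)
    if bw_pre <= 0 or bw_post <= 0:
        return _fallback(0)
    K_pre = _kernel_matrix(x, bw_pre)
    K_post = _kernel_matrix(x, bw_post)

    theta = float(r.mean())
    n_it = 0
    converged = False
    for n_it in range(1, max_iterations + 1):
        w_post, w_pre = r, (1.0 - r) * ctl
        if w_post.sum() < 2.0 or w_pre.sum() < 2.0:
            return _fallback(n_it)
        d_pre = _floor(K_pre @ (w_pre / w_pre.sum()))
        d_post = _floor(K_post @ (w_post / w_post.sum()))
        if not (np.all(np.isfinite(d_pre)) and np.all(np.isfinite(d_post))):
            raise FloatingPointError(f"marker {marker!r}: non-finite density in fit")
        num = theta * d_post
        r_new = num / (num + (1.0 - theta) * d_pre)
        r_new[forced] = 0.0
        theta = float(r_new.mean())
        delta = float(np.max(np.abs(r_new - r)))
        r = r_new
        if delta < tolerance:
            converged = True
            break

    w_post, w_pre = r, (1.0 - r) * ctl
    if w_post.sum() < 2.0 or w_pre.sum() < 2.0:
        return _fallback(n_it)
    f_pre = _make_kde(x, w_pre, bw_pre)
    f_post = _make_kde(x, w_post, bw_post)
    ll = float(np.sum(np.log(_floor(theta * f_post(x) + (1 - theta) * f_pre(x)))))
    return EventDistribution(
        marker=marker, f_pre=f_pre, f_post=f_post, theta=theta,
        converged=converged, fallback=False, n_iterations=n_it,
        log_likelihood=ll, values=x, control_mask=ctl.astype(bool),
        responsibilities=r, constraint=constraint,
    )


def event_probability(dist: EventDistribution, x) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate (f_pre(x), f_post(x)), floored at 1e-12.

    Missing observations return (1, 1): a missing marker is uninformative
    for that subject, contributing nothing to the stage likelihood.  For
    single-component fallbacks the post density equals the pre density.
    """
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    p_pre = np.ones_like(x)
    p_post = np.ones_like(x)
    obs = np.isfinite(x)
    if obs.any():
        pre = _floor(np.asarray(dist.f_pre(x[obs])))
        post = pre if dist.f_post is None else _floor(np.asarray(dist.f_post(x[obs])))
        p_pre[obs] = pre
        p_post[obs] = post
    if scalar:
        return float(p_pre[0]), float(p_post[0])
    return p_pre, p_post


def has_disease_signal(dist: EventDistribution) -> bool:
    """Decide whether the fitted mixture discerns disease signal.

    A marker is excluded (returns False) when any of:

    a. the fit fell back to a single component (the post-event weight
       collapsed — the data cannot sustain an abnormal component);
    b. the mean post-event responsibility among patients is below 0.05
       (essentially no patient looks abnormal);
    c. the median of post-responsible values does not exceed the median of
       pre-responsible values on the oriented scale (the "abnormal"
       component is not actually more abnormal).
    """
    if dist.fallback or dist.f_post is None:
        return False
    r = dist.responsibilities
    patients = ~dist.control_mask
    if patients.sum() == 0 or float(r[patients].mean()) < 0.05:
        return False
    post_vals = dist.values[r > 0.5]
    pre_vals = dist.values[r <= 0.5]
    if len(post_vals) == 0 or len(pre_vals) == 0:
        return False
    return float(np.median(post_vals)) > float(np.median(pre_vals))
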