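"""Fixed-shape mixture deconvolution of a length distribution.

The observed length distribution of a microsatellite is modelled as a
mixture of up to three copies of the empirical reference shape, each
translated to its own mean: one component for the stable allele and up to
two for unstable alleles.  The free parameters are the component means
m1..m3 and proportions P1..P3; they are fitted by Expectation-Maximisation
on the binned counts (the histogram is a sufficient statistic, so the
likelihood is identical to the per-read formulation at a fraction of the
cost).

The expected complete-data log-likelihood is separable: the proportion
update is the classical responsibility fraction, and each component mean
is relocated by a one-dimensional search (integer-translation grid plus
bounded refinement, seeded with the responsibility-weighted mean).  Every
update maximises its share of the EM surrogate, so the log-likelihood is
monotone by construction even for skewed stutter shapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .extraction import LengthHistogram
from .profiles import ReferenceProfile, shift_profile


@dataclass(frozen=True)
class EMConfig:
    """Hyperparameters of the EM fit.

    ``init_offsets`` places the candidate unstable components below the
    reference mean by default, reflecting the deletion bias of poly-A
    instability; restarts jitter these offsets (seeded) so insertions are
    explored too.
    """

    max_iterations: int = 500
    loglik_tolerance: float = 1e-6
    n_restarts: int = 3
    init_offsets: tuple[float, ...] = (-5.0, -10.0)
    init_proportions: tuple[float, ...] = (0.90, 0.05, 0.05)
    jitter_sd: float = 2.0
    collapse_distance: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.loglik_tolerance <= 0:
            raise ValueError("loglik_tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be at least 1")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be at least 1")


@dataclass(frozen=True)
class MixtureFit:
    """Fitted mixture parameters {m1..mk, P1..Pk} with fit diagnostics."""

    means: tuple[float, ...]
    proportions: tuple[float, ...]
    log_likelihood: float
    n_iterations: int
    converged: bool
    loglik_trace: tuple[float, ...] = field(default=(), repr=False)

    def __post_init__(self) -> None:
        if len(self.means) != len(self.proportions) or not self.means:
            raise ValueError("means and proportions must be non-empty and matched")
        if any(p < -1e-12 for p in self.proportions):
            raise ValueError("proportions must be non-negative")
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")


def mixture_pmf(fit: MixtureFit, profile: ReferenceProfile) -> dict[int, float]:
    """Pointwise mixture distribution: sum of P_n-weighted shifted profiles."""
    out: dict[int, float] = {}
    for mean, proportion in zip(fit.means, fit.proportions):
        if proportion == 0.0:
            continue
        for length, p in shift_profile(profile, mean).items():
            out[length] = out.get(length, 0.0) + proportion * p
    return dict(sorted(out.items()))


def _histogram_arrays(histogram: LengthHistogram) -> tuple[np.ndarray, np.ndarray]:
    if histogram.n_reads < 1:
        raise ValueError(f"histogram for {histogram.locus} is empty")
    lengths = np.fromiter(histogram.counts.keys(), dtype=int)
    counts = np.fromiter(histogram.counts.values(), dtype=float)
    return lengths, counts


def _component_matrix(
    profile: ReferenceProfile, means: Sequence[float], x: np.ndarray
) -> np.ndarray:
    return np.vstack([profile.component_pmf(x, m) for m in means])


def _loglik(
    w: np.ndarray, comp: np.ndarray, proportions: np.ndarray
) -> float:
    mix = proportions @ comp
    with np.errstate(divide="ignore"):
        logmix = np.log(mix)
    return float(np.dot(w, logmix))


def log_likelihood(
    histogram: LengthHistogram, fit: MixtureFit, profile: ReferenceProfile
) -> float:
    """Binned log-likelihood: sum over lengths of count * log(mixture pmf).

    Finite as long as the profile carries a pseudocount floor.
    """
    x, w = _histogram_arrays(histogram)
    comp = _component_matrix(profile, fit.means, x)
    return _loglik(w, comp, np.asarray(fit.proportions))


def _collapse(
    means: np.ndarray, proportions: np.ndarray, min_distance: float
) -> tuple[np.ndarray, np.ndarray]:
    """Merge components closer than ``min_distance`` nt (proportion-weighted)."""
    order = np.argsort(means)
    means, proportions = means[order].copy(), proportions[order].copy()
    while means.size > 1:
        gaps = np.diff(means)
        j = int(np.argmin(gaps))
        if gaps[j] >= min_distance:
            break
        total = proportions[j] + proportions[j + 1]
        merged_mean = (
            (means[j] * proportions[j] + means[j + 1] * proportions[j + 1]) / total
            if total > 0
            else 0.5 * (means[j] + means[j + 1])
        )
        means = np.delete(means, j + 1)
        proportions = np.delete(proportions, j + 1)
        means[j] = merged_mean
        proportions[j] = total
    return means, proportions


def _q_component(
    profile: ReferenceProfile, x: np.ndarray, wr: np.ndarray, mean: float
) -> float:
    """Component share of the EM surrogate: sum_i w_i r_ni log f(x_i; m)."""
    f = profile.component_pmf(x, mean)
    with np.errstate(divide="ignore"):
        logf = np.log(f)
    return float(np.dot(wr, logf))


def _grid_log_matrix(
    profile: ReferenceProfile, x: np.ndarray, mean_bounds: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Log component pmf at every integer translation within bounds,
    evaluated at the observed lengths; precomputed once per fit so the
    M-step grid scan is a single mat-vec."""
    lo, hi = mean_bounds
    base = profile.mean
    shifts = np.arange(int(np.ceil(lo - base)), int(np.floor(hi - base)) + 1)
    with np.errstate(divide="ignore"):
        log_matrix = np.vstack(
            [np.log(profile.component_pmf(x, base + s)) for s in shifts]
        ) if shifts.size else np.empty((0, x.size))
    return shifts, log_matrix


def _refine_component_mean(
    profile: ReferenceProfile,
    x: np.ndarray,
    wr: np.ndarray,
    current: float,
    moment: float,
    anchor: float,
    anchor_q: float,
    mean_bounds: tuple[float, float],
) -> float:
    """Fractional polish of one component mean around the best integer
    anchor: bounded 1-D maximisation of the component surrogate, with the
    current and moment means kept as candidates so the surrogate never
    decreases."""
    from scipy.optimize import minimize_scalar

    lo, hi = mean_bounds
    candidates = [
        (anchor, anchor_q),
        (current, _q_component(profile, x, wr, current)),
        (moment, _q_component(profile, x, wr, moment)),
    ]
    best_m, best_q = max(candidates, key=lambda mq: mq[1])
    span_lo, span_hi = max(lo, best_m - 1.0), min(hi, best_m + 1.0)
    if span_hi > span_lo:
        result = minimize_scalar(
            lambda m: -_q_component(profile, x, wr, m),
            bounds=(span_lo, span_hi),
            method="bounded",
            options={"xatol": 1e-3, "maxiter": 30},
        )
        if -result.fun > best_q:
            best_m = float(result.x)
    return best_m


def _run_em(
    x: np.ndarray,
    w: np.ndarray,
    profile: ReferenceProfile,
    means0: np.ndarray,
    props0: np.ndarray,
    config: EMConfig,
    mean_bounds: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray, float, int, bool, list[float]]:
    W = w.sum()
    shifts, log_matrix = _grid_log_matrix(profile, x, mean_bounds)
    means = np.clip(means0.astype(float), *mean_bounds)
    props = props0.astype(float) / props0.sum()
    comp = _component_matrix(profile, means, x)
    ll = _loglik(w, comp, props)
    trace = [ll]
    converged = False
    iteration = 0
    lo, hi = mean_bounds
    base = profile.mean
    # Two-phase schedule: integer-resolution location updates until the
    # log-likelihood plateaus, then fractional refinement to convergence.
    # Every accepted update maximises its surrogate share (or keeps the
    # previous mean), so monotonicity is unaffected.  The fractional
    # polish is re-run only when a component's best integer anchor moves:
    # during the slow proportion-decay tail of EM the means are
    # stationary and each iteration reduces to array arithmetic.
    refine = False
    refined: dict[int, tuple[int, float]] = {}  # comp -> (anchor index, mean)
    for iteration in range(1, config.max_iterations + 1):
        # E-step
        weighted = comp * props[:, None]
        mix = weighted.sum(axis=0)
        resp = weighted / mix[None, :]
        resp_mass = resp @ w
        # M-step: the surrogate separates into the proportion update and
        # one 1-D location problem per component.
        props = np.maximum(resp_mass / W, 0.0)
        props = props / props.sum()
        with np.errstate(invalid="ignore"):
            moment = (resp * x[None, :]) @ w / resp_mass
        new_means = means.copy()
        for n in range(means.size):
            if resp_mass[n] <= 1e-12 or not shifts.size:
                continue
            wr = resp[n] * w
            grid_q = log_matrix @ wr
            gi = int(np.argmax(grid_q))
            anchor = float(base + shifts[gi])
            current = float(np.clip(means[n], lo, hi))
            if not refine:
                # integer phase: move to the best translation unless the
                # (possibly fractional) current mean is better
                on_grid = abs(current - base - round(current - base)) < 1e-9
                if on_grid:
                    current_q = float(
                        grid_q[int(round(current - base)) - int(shifts[0])]
                    ) if shifts[0] <= round(current - base) <= shifts[-1] else -np.inf
                else:
                    current_q = _q_component(profile, x, wr, current)
                new_means[n] = anchor if grid_q[gi] >= current_q else current
            else:
                cached = refined.get(n)
                if cached is not None and cached[0] == gi:
                    new_means[n] = cached[1]
                else:
                    new_means[n] = _refine_component_mean(
                        profile, x, wr, current,
                        float(np.clip(moment[n], lo, hi)),
                        anchor, float(grid_q[gi]), mean_bounds,
                    )
                    refined[n] = (gi, float(new_means[n]))
        if not np.array_equal(new_means, means):
            means = new_means
            comp = _component_matrix(profile, means, x)
        ll_new = _loglik(w, comp, props)
        trace.append(ll_new)
        if ll_new - ll < config.loglik_tolerance:
            ll = ll_new
            if refine:
                converged = True
                break
            refine = True
            refined.clear()
        else:
            ll = ll_new
    return means, props, ll, iteration, converged, trace


def em_fit(
    histogram: LengthHistogram,
    profile: ReferenceProfile,
    k: int = 3,
    config: EMConfig = EMConfig(),
    mean_bounds: Optional[tuple[float, float]] = None,
    init_means: Optional[Sequence[float]] = None,
    init_proportions: Optional[Sequence[float]] = None,
) -> MixtureFit:
    """Maximum-likelihood mixture fit with k <= 3 shifted-reference components.

    Component 1 starts at the reference mean with the bulk of the mass;
    further components start below it (``config.init_offsets``), with
    jittered restarts.  The best restart (highest final log-likelihood
    after collapsing near-duplicate components) is returned.
    ``mean_bounds`` restricts component means to an interval, used to fit
    the stable-only reduced model of the likelihood-ratio test.
    """
    if k not in (1, 2, 3):
        raise ValueError("k must be 1, 2 or 3")
    x, w = _histogram_arrays(histogram)
    if mean_bounds is None:
        mean_bounds = (float(profile.lengths[0]), float(profile.lengths[-1]))
    rng = np.random.default_rng(config.seed)

    base_means = [profile.mean] + [
        profile.mean + off for off in config.init_offsets[: k - 1]
    ]
    while len(base_means) < k:
        base_means.append(profile.mean - 5.0 * len(base_means))
    base_props = np.asarray(config.init_proportions[:k], dtype=float)
    if base_props.size < k:
        base_props = np.full(k, 1.0 / k)

    starts = []
    if init_means is not None:
        given_props = (
            np.asarray(init_proportions, dtype=float)
            if init_proportions is not None
            else np.full(len(init_means), 1.0 / len(init_means))
        )
        starts.append((np.asarray(init_means, dtype=float), given_props))
    starts.append((np.asarray(base_means, dtype=float), base_props))
    while len(starts) < config.n_restarts + (1 if init_means is not None else 0):
        jittered = np.asarray(base_means) + np.concatenate(
            ([0.0], rng.normal(0.0, config.jitter_sd, size=k - 1))
        )
        starts.append((jittered, base_props))

    best: Optional[MixtureFit] = None
    for means0, props0 in starts:
        means, props, _, n_iter, converged, trace = _run_em(
            x, w, profile, means0, props0, config, mean_bounds
        )
        means, props = _collapse(means, props, config.collapse_distance)
        comp = _component_matrix(profile, means, x)
        ll = _loglik(w, comp, props)
        fit = MixtureFit(
            means=tuple(float(m) for m in means),
            proportions=tuple(float(p) for p in props),
            log_likelihood=ll,
            n_iterations=n_iter,
            converged=converged,
            loglik_trace=tuple(trace),
        )
        if best is None or fit.log_likelihood > best.log_likelihood:
            best = fit
    assert best is not None
    return best
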