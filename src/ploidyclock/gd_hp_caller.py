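"""Genome-doubling and partial-haploidisation calling.

GD is detected cohort-wide by fitting a one-dimensional Gaussian mixture
(expectation-maximisation, BIC model selection over K in {1,2,3}) to the
per-sample major-allele ploidy. A sample is called genome doubled when it
is assigned to a mixture component whose mean major-allele ploidy is at
least ``gd_boundary`` (default 1.6, midway-with-margin between the
theoretical diploid value 1.0 and the doubled value 2.0). Cohorts smaller
than ``min_cohort`` samples fall back to thresholding the per-sample
feature directly; the method used is recorded on every call.

HP (partial haploidisation) is a pure threshold: LOH fraction strictly
greater than 0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .copy_state import PloidyProfile

GD_BOUNDARY = 1.6
HP_THRESHOLD = 0.5
MIN_COHORT_FOR_MIXTURE = 10
_VAR_FLOOR = 1e-6


class SmallCohortError(ValueError):
    """Raised when a mixture fit is requested on too few samples."""


@dataclass
class MixtureFit:
    """A fitted 1-D Gaussian mixture with its BIC model-selection trace."""

    k: int
    means: np.ndarray
    variances: np.ndarray
    weights: np.ndarray
    log_likelihood: float
    bic: dict[int, float]
    loglik_trace: list[float] = field(default_factory=list)

    def responsibilities(self, x: np.ndarray) -> np.ndarray:
        log_r = _log_component_densities(x, self.means, self.variances, self.weights)
        log_norm = _logsumexp_rows(log_r)
        return np.exp(log_r - log_norm[:, None])


@dataclass
class GDCall:
    sample_id: str
    gd: bool
    component_mean: float
    posterior: float
    method: str  # "mixture" | "fallback_threshold"


def _log_component_densities(
    x: np.ndarray, means: np.ndarray, variances: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    # (n, K) matrix of log(w_k * N(x_i; mu_k, var_k))
    var = np.maximum(variances, _VAR_FLOOR)
    return (
        np.log(weights)[None, :]
        - 0.5 * np.log(2.0 * np.pi * var)[None, :]
        - 0.5 * (x[:, None] - means[None, :]) ** 2 / var[None, :]
    )


def _logsumexp_rows(a: np.ndarray) -> np.ndarray:
    m = a.max(axis=1)
    return m + np.log(np.exp(a - m[:, None]).sum(axis=1))


def _init_means(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    # k-means++-style seeding: first centre uniform, then distance-weighted.
    means = [x[rng.integers(len(x))]]
    for _ in range(1, k):
        d2 = np.min((x[:, None] - np.array(means)[None, :]) ** 2, axis=1)
        if d2.sum() <= 0:
            means.append(x[rng.integers(len(x))])
        else:
            means.append(x[rng.choice(len(x), p=d2 / d2.sum())])
    return np.array(means, dtype=float)


def _em_once(
    x: np.ndarray, k: int, rng: np.random.Generator, tol: float, max_iter: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, list[float]]:
    n = len(x)
    means = _init_means(x, k, rng)
    variances = np.full(k, max(float(np.var(x)) / k, _VAR_FLOOR))
    weights = np.full(k, 1.0 / k)
    prev_ll = -np.inf
    trace: list[float] = []
    for _ in range(max_iter):
        log_r = _log_component_densities(x, means, variances, weights)
        log_norm = _logsumexp_rows(log_r)
        ll = float(log_norm.sum())
        trace.append(ll)
        resp = np.exp(log_r - log_norm[:, None])
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        means = (resp * x[:, None]).sum(axis=0) / nk
        variances = np.maximum(
            (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk, _VAR_FLOOR
        )
        weights = nk / n
        if ll - prev_ll < tol and np.isfinite(prev_ll):
            break
        prev_ll = ll
    return means, variances, weights, trace[-1], trace


def fit_ploidy_mixture(
    profiles: Sequence[PloidyProfile],
    k_candidates: Iterable[int] = (1, 2, 3),
    seed: int = 0,
    n_restarts: int = 20,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> MixtureFit:
    """Fit a 1-D Gaussian mixture to major-allele ploidy, selecting K by BIC.

    Deterministic given ``seed`` (seeded k-means++-style initialisation,
    ``n_restarts`` restarts, convergence tolerance ``tol`` on the
    log-likelihood). Requires at least :data:`MIN_COHORT_FOR_MIXTURE`
    samples; smaller cohorts must use the fallback threshold rule in
    :func:`call_gd`.
    """
    x = np.asarray([p.major_ploidy for p in profiles], dtype=float)
    if len(x) < MIN_COHORT_FOR_MIXTURE:
        raise SmallCohortError(
            f"mixture fit needs >= {MIN_COHORT_FOR_MIXTURE} samples, got {len(x)};"
            " use call_gd(profiles, fit=None) for the threshold fallback"
        )
    rng = np.random.default_rng(seed)
    best: dict[int, tuple] = {}
    bic: dict[int, float] = {}
    for k in sorted(k_candidates):
        if k < 1 or k > len(x):
            continue
        best_ll = -np.inf
        best_fit = None
        for _ in range(n_restarts):
            means, variances, weights, ll, trace = _em_once(x, k, rng, tol, max_iter)
            if ll > best_ll:
                best_ll = ll
                best_fit = (means, variances, weights, ll, trace)
        assert best_fit is not None
        n_params = 3 * k - 1  # means + variances + free weights
        bic[k] = -2.0 * best_ll + n_params * math.log(len(x))
        best[k] = best_fit
    k_sel = min(bic, key=lambda k: (bic[k], k))
    means, variances, weights, ll, trace = best[k_sel]
    order = np.argsort(means)
    return MixtureFit(
        k=k_sel,
        means=means[order],
        variances=variances[order],
        weights=weights[order],
        log_likelihood=ll,
        bic=bic,
        loglik_trace=trace,
    )


def call_gd(
    profiles: Sequence[PloidyProfile],
    fit: MixtureFit | None = None,
    gd_boundary: float = GD_BOUNDARY,
) -> list[GDCall]:
    """Call genome doubling per sample.

    With a mixture fit, a sample is GD iff its maximum-posterior component
    has mean major-allele ploidy >= ``gd_boundary``. Without a fit (small
    cohorts), the per-sample feature is thresholded directly.
    """
    calls: list[GDCall] = []
    if fit is not None:
        x = np.asarray([p.major_ploidy for p in profiles], dtype=float)
        resp = fit.responsibilities(x)
        assigned = resp.argmax(axis=1)
        for i, profile in enumerate(profiles):
            comp = int(assigned[i])
            calls.append(
                GDCall(
                    sample_id=profile.sample_id,
                    gd=bool(fit.means[comp] >= gd_boundary),
                    component_mean=float(fit.means[comp]),
                    posterior=float(resp[i, comp]),
                    method="mixture",
                )
            )
    else:
        for profile in profiles:
            calls.append(
                GDCall(
                    sample_id=profile.sample_id,
                    gd=bool(profile.major_ploidy >= gd_boundary),
                    component_mean=float(profile.major_ploidy),
                    posterior=1.0,
                    method="fallback_threshold",
                )
            )
    for call, profile in zip(calls, profiles):
        profile.gd = call.gd
    return calls


def call_gd_cohort(
    profiles: Sequence[PloidyProfile],
    min_cohort: int = MIN_COHORT_FOR_MIXTURE,
    gd_boundary: float = GD_BOUNDARY,
    seed: int = 0,
) -> tuple[list[GDCall], MixtureFit | None]:
    """Mixture-based GD calling with automatic small-cohort fallback."""
    fit = None
    if len(profiles) >= min_cohort:
        fit = fit_ploidy_mixture(profiles, seed=seed)
    return call_gd(profiles, fit, gd_boundary=gd_boundary), fit


def call_hp(profile: PloidyProfile, threshold: float = HP_THRESHOLD) -> bool:
    """HP rule: LOH fraction strictly greater than the threshold (0.5)."""
    hp = profile.loh_fraction > threshold
    profile.hp = hp
    return hp


def hp_gd_cooccurrence(
    gd_calls: Sequence[GDCall], hp_flags: Mapping[str, bool]
) -> dict[str, float | int]:
    """2x2 GD x HP co-occurrence counts plus the HP-with-GD fraction."""
    counts = {"gd_hp": 0, "gd_only": 0, "hp_only": 0, "neither": 0}
    for call in gd_calls:
        hp = bool(hp_flags[call.sample_id])
        if call.gd and hp:
            counts["gd_hp"] += 1
        elif call.gd:
            counts["gd_only"] += 1
        elif hp:
            counts["hp_only"] += 1
        else:
            counts["neither"] += 1
    n_hp = counts["gd_hp"] + counts["hp_only"]
    summary: dict[str, float | int] = dict(counts)
    summary["frac_hp_with_gd"] = counts["gd_hp"] / n_hp if n_hp else float("nan")
    return summary
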