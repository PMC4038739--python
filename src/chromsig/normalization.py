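"""Interaction-frequency normalization.

Raw 5C array signal confounds true contact frequency with two technical
factors: a per-array scale (how much DNA hybridized) and per-primer
efficiencies (each fragment's forward/reverse primer amplifies and
hybridizes with its own efficiency, so a contact (i, j) is attenuated by
the product of two fragment-level factors).  Normalization therefore has
two multiplicative stages:

1. iterative proportional fitting of per-fragment efficiency factors, so
   that after dividing cell (i, j) by ``f_i * f_j`` every fragment's mean
   measured IF equals the global mean;
2. scaling the whole matrix to a fixed total (IF units are relative, so
   the target is an arbitrary constant).

Both stages are ratio-based, which makes the pipeline exactly invariant to
rescaling the raw input.  Unmeasured cells are excluded from every mean and
sum and are never imputed here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import ContactMatrix
from .errors import DegenerateDataError, ValidationError


@dataclass(frozen=True)
class NormalizationConfig:
    target_total: float = 1e6
    max_iter: int = 200
    tol: float = 1e-8
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValidationError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValidationError("tol must be positive")
        if self.target_total <= 0:
            raise ValidationError("target_total must be positive")
        if self.pseudocount < 0:
            raise ValidationError("pseudocount must be nonnegative")


@dataclass
class NormalizationResult:
    normalized: ContactMatrix
    array_scale: float
    primer_efficiency: np.ndarray  # per fragment, geometric mean 1
    iterations: int
    converged: bool


def scale_to_total(
    raw: ContactMatrix, target_total: float = 1e6
) -> tuple[ContactMatrix, float]:
    """Scale so the measured upper-triangle sum equals ``target_total``.

    Returns the scaled matrix and the applied factor
    ``array_scale = target_total / raw_sum``.
    """
    total = raw.measured_sum(upper_only=True, include_diagonal=True)
    if not total > 0:
        raise DegenerateDataError("matrix has no positive measured signal")
    scale = target_total / total
    out = raw.copy()
    out.values = out.values * scale
    return out, scale


def estimate_primer_efficiencies(
    raw: ContactMatrix, cfg: NormalizationConfig = NormalizationConfig()
) -> tuple[np.ndarray, int, bool]:
    """Iterative proportional fitting of per-fragment efficiency factors.

    Each round, fragment i's factor update is (mean of its measured cells) /
    (global measured mean); cells are divided by ``u_i * u_j``.  Stops when
    every update is within ``tol`` of 1, or at ``max_iter`` (flagged, not
    raised).  Accumulated factors are renormalized to geometric mean 1.
    """
    W = raw.values.copy()
    mask = raw.mask
    n = raw.n
    per_row = mask.sum(axis=1)
    if np.any(per_row == 0):
        missing = np.where(per_row == 0)[0] + 1
        raise DegenerateDataError(
            f"fragments {missing.tolist()} have no measured contacts"
        )
    row_pos = np.nansum(np.where(mask, W, 0.0), axis=1)
    if np.any(row_pos <= 0):
        bad = np.where(row_pos <= 0)[0] + 1
        raise DegenerateDataError(
            f"fragments {bad.tolist()} have no positive measured contact"
        )

    factors = np.ones(n)
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        with np.errstate(invalid="ignore"):
            row_mean = np.nanmean(W, axis=1)
            global_mean = np.nanmean(W[mask])
        u = row_mean / global_mean
        W = W / np.outer(u, u)
        factors = factors * u
        if np.max(np.abs(u - 1.0)) < cfg.tol:
            converged = True
            break
    factors = factors / np.exp(np.mean(np.log(factors)))
    return factors, it, converged


def normalize_sample(
    raw: ContactMatrix, cfg: NormalizationConfig = NormalizationConfig()
) -> NormalizationResult:
    """Full per-sample pipeline: optional pseudocount, primer-efficiency
    correction, then array scaling.  The unmeasured mask is preserved."""
    work = raw.copy()
    if cfg.pseudocount > 0:
        work.values = np.where(work.mask, work.values + cfg.pseudocount, np.nan)
    factors, iterations, converged = estimate_primer_efficiencies(work, cfg)
    corrected = work.copy()
    corrected.values = corrected.values / np.outer(factors, factors)
    scaled, scale = scale_to_total(corrected, cfg.target_total)
    return NormalizationResult(
        normalized=scaled,
        array_scale=scale,
        primer_efficiency=factors,
        iterations=iterations,
        converged=converged,
    )


def normalize_panel(panel, cfg: NormalizationConfig = NormalizationConfig()):
    """Normalize every sample of a panel; returns (panel, list of results)."""
    from dataclasses import replace

    from .data_model import SamplePanel

    results = []
    samples = []
    for s in panel:
        res = normalize_sample(s.matrix, cfg)
        results.append(res)
        samples.append(replace(s, matrix=res.normalized))
    return SamplePanel(samples, panel.fragment_map), results
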