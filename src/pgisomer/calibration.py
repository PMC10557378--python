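"""Isomer prediction model: polynomial calibration, closure, cross-validation.

The model couples two least-squares fits trained on mixtures of known
composition:

* a second-degree polynomial **surface** z = f(x, y) predicting %Δ12-PGD₂
  from the relative abundances x = r331 and y = r341 of the diagnostic MS³
  channels, and
* a third-degree polynomial **curve** r331 = g(%PGE₂), inverted numerically
  at prediction time to obtain %PGE₂.

%PGD₂ is obtained by closure (100 − %PGE₂ − %Δ12-PGD₂), so the three
percentages of every valid prediction sum to exactly 100.  Raw predictions
must fall inside [−10, 110] % or the composition is flagged invalid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from numpy.polynomial import polynomial as P

from .spectra import TripletAbundance

__all__ = [
    "IsomerComposition",
    "TrainingSample",
    "IsomerModel",
    "CVResult",
    "fit_model",
    "predict",
    "invert_cubic",
    "cross_validate",
    "RAW_RANGE",
]

#: Admissible range for raw (pre-closure) percentage predictions.
RAW_RANGE = (-10.0, 110.0)

#: Grid step (%) for the coarse search used to disambiguate cubic roots.
GRID_STEP = 0.01

ISOMERS = ("PGE2", "PGD2", "d12-PGD2")


@dataclass(frozen=True)
class IsomerComposition:
    """Percentages of PGE₂, PGD₂ and Δ12-PGD₂; valid compositions close to 100."""

    pge2_pct: float
    pgd2_pct: float
    d12pgd2_pct: float
    valid: bool = True

    def as_array(self) -> np.ndarray:
        return np.array([self.pge2_pct, self.pgd2_pct, self.d12pgd2_pct])

    @staticmethod
    def of(pge2: float, pgd2: float, d12: float) -> "IsomerComposition":
        """A ground-truth composition; must be non-negative and sum to 100."""
        if min(pge2, pgd2, d12) < 0:
            raise ValueError("composition percentages must be non-negative")
        if abs(pge2 + pgd2 + d12 - 100.0) > 1e-6:
            raise ValueError(f"composition must sum to 100, got {pge2 + pgd2 + d12}")
        return IsomerComposition(pge2, pgd2, d12)


@dataclass(frozen=True)
class TrainingSample:
    true_composition: IsomerComposition
    triplet: TripletAbundance
    replicate: int = 0


@dataclass
class IsomerModel:
    """Fitted calibration: 6 surface + 4 cubic coefficients with diagnostics.

    ``surface_coeffs`` = (p00, p10, p01, p20, p11, p02) for
    z = p00 + p10·x + p01·y + p20·x² + p11·x·y + p02·y²;
    ``cubic_coeffs`` = (c0, c1, c2, c3) in ascending powers of %PGE₂.
    """

    surface_coeffs: np.ndarray
    cubic_coeffs: np.ndarray
    r2_surface: float
    r2_cubic: float
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.surface_coeffs = np.asarray(self.surface_coeffs, dtype=float)
        self.cubic_coeffs = np.asarray(self.cubic_coeffs, dtype=float)
        if self.surface_coeffs.shape != (6,):
            raise ValueError("surface_coeffs must have exactly 6 entries")
        if self.cubic_coeffs.shape != (4,):
            raise ValueError("cubic_coeffs must have exactly 4 entries")

    def surface(self, x, y):
        """Evaluate the %Δ12-PGD₂ surface at (r331, r341)."""
        p00, p10, p01, p20, p11, p02 = self.surface_coeffs
        return p00 + p10 * x + p01 * y + p20 * x * x + p11 * x * y + p02 * y * y

    def cubic(self, pge2_pct):
        """Evaluate the expected r331 at a given %PGE₂."""
        return P.polyval(pge2_pct, self.cubic_coeffs)

    # -- plain-text (JSON) serialization -----------------------------------
    def save(self, path: str) -> None:
        record = {
            "format": "pgisomer-model-v1",
            "surface_coeffs": self.surface_coeffs.tolist(),
            "cubic_coeffs": self.cubic_coeffs.tolist(),
            "r2_surface": self.r2_surface,
            "r2_cubic": self.r2_cubic,
            "training_meta": self.training_meta,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(record, fh, indent=2)
            fh.write("\n")

    @staticmethod
    def load(path: str) -> "IsomerModel":
        with open(path, encoding="utf-8") as fh:
            record = json.load(fh)
        if record.get("format") != "pgisomer-model-v1":
            raise ValueError(f"{path}: not a pgisomer model file")
        return IsomerModel(
            surface_coeffs=np.array(record["surface_coeffs"]),
            cubic_coeffs=np.array(record["cubic_coeffs"]),
            r2_surface=float(record["r2_surface"]),
            r2_cubic=float(record["r2_cubic"]),
            training_meta=record.get("training_meta", {}),
        )


@dataclass(frozen=True)
class CVResult:
    rmse_pge2: float
    rmse_pgd2: float
    rmse_d12: float
    n_iterations: int
    holdout_fraction: float
    seed: int

    def as_dict(self) -> dict:
        return asdict(self)


def _r2(observed: np.ndarray, fitted: np.ndarray) -> float:
    ss_res = float(np.sum((observed - fitted) ** 2))
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res < 1e-12 else 0.0
    return 1.0 - ss_res / ss_tot


def fit_model(samples: Sequence[TrainingSample]) -> IsomerModel:
    """Least-squares fit of the surface and cubic to calibration mixtures.

    Requires at least 10 samples with non-degenerate spread in (r331, r341)
    and in %PGE₂.  Replicates enter as separate, unweighted samples.
    """
    samples = list(samples)
    if len(samples) < 10:
        raise ValueError(f"need at least 10 training samples, got {len(samples)}")
    bad = [i for i, s in enumerate(samples) if not s.triplet.defined]
    if bad:
        raise ValueError(f"samples with zero total channel intensity: {bad}")

    x = np.array([s.triplet.r331 for s in samples])
    y = np.array([s.triplet.r341 for s in samples])
    z = np.array([s.true_composition.d12pgd2_pct for s in samples])
    p = np.array([s.true_composition.pge2_pct for s in samples])

    if np.std(p) < 1e-9 or np.std(x) < 1e-12:
        raise ValueError("degenerate training design: no spread in composition")

    design = np.column_stack([np.ones_like(x), x, y, x * x, x * y, y * y])
    if np.linalg.matrix_rank(design) < 6:
        raise ValueError("rank-deficient design: calibration compositions are collinear")
    surface_coeffs, *_ = np.linalg.lstsq(design, z, rcond=None)

    cubic_coeffs = P.polyfit(p, x, 3)

    model = IsomerModel(
        surface_coeffs=surface_coeffs,
        cubic_coeffs=cubic_coeffs,
        r2_surface=_r2(z, design @ surface_coeffs),
        r2_cubic=_r2(x, P.polyval(p, cubic_coeffs)),
        training_meta={"n_samples": len(samples)},
    )
    return model


def invert_cubic(model: IsomerModel, r331: float, raw_range=RAW_RANGE) -> float | None:
    """Solve g(%PGE₂) = r331 for the admissible real root.

    Real roots inside ``raw_range`` are candidates; roots inside [0, 100] are
    preferred.  When several candidates remain, the one nearest the coarse
    grid-search minimizer of |g(p) − r331| (step 0.01 %) is chosen.  Returns
    ``None`` when no admissible root exists.
    """
    c = model.cubic_coeffs.copy()
    c[0] -= r331
    roots = P.polyroots(c)
    real = roots[np.abs(roots.imag) < 1e-8].real
    lo, hi = raw_range
    eps = 1e-9
    candidates = real[(real >= lo - eps) & (real <= hi + eps)]
    if candidates.size == 0:
        return None
    preferred = candidates[(candidates >= -eps) & (candidates <= 100.0 + eps)]
    pool = preferred if preferred.size else candidates
    if pool.size == 1:
        return float(np.clip(pool[0], lo, hi))
    g_lo, g_hi = (0.0, 100.0) if preferred.size else (lo, hi)
    grid = np.arange(g_lo, g_hi + GRID_STEP / 2, GRID_STEP)
    p_star = grid[np.argmin(np.abs(P.polyval(grid, model.cubic_coeffs) - r331))]
    return float(np.clip(pool[np.argmin(np.abs(pool - p_star))], lo, hi))


def predict(model: IsomerModel, t: TripletAbundance) -> IsomerComposition:
    """Predict an isomer composition from a diagnostic-channel triplet.

    Prediction order follows the calibration design: %PGE₂ from the cubic
    inversion, %Δ12-PGD₂ from the surface, %PGD₂ by closure.  The result is
    invalid when any raw value leaves [−10, 110] % or no admissible cubic
    root exists; valid results sum to exactly 100.
    """
    if not t.defined:
        raise ValueError("triplet has zero total intensity; relative abundances undefined")
    pge2 = invert_cubic(model, t.r331)
    d12 = float(model.surface(t.r331, t.r341))
    lo, hi = RAW_RANGE
    if pge2 is None:
        return IsomerComposition(np.nan, np.nan, np.nan, valid=False)
    pgd2 = 100.0 - pge2 - d12
    valid = all(lo <= v <= hi for v in (pge2, d12, pgd2))
    return IsomerComposition(pge2, pgd2, d12, valid=valid)


def cross_validate(
    samples: Sequence[TrainingSample],
    holdout_fraction: float = 0.1,
    n_iterations: int = 50,
    seed: int = 0,
) -> CVResult:
    """Repeated random hold-out validation of the calibration model.

    Per iteration a random ``holdout_fraction`` of the samples (at least one)
    is kept for testing, the model is fitted on the rest, and the per-isomer
    RMSE of predicted vs true percentages is computed over the holdout.  The
    reported RMSEs are means over iterations, per isomer.
    """
    samples = list(samples)
    n = len(samples)
    n_hold = max(1, int(round(holdout_fraction * n)))
    if n - n_hold < 10:
        raise ValueError("too few samples to fit after holdout split")
    rng = np.random.default_rng(seed)
    per_iter = np.zeros((n_iterations, 3))
    for it in range(n_iterations):
        order = rng.permutation(n)
        hold, train = order[:n_hold], order[n_hold:]
        model = fit_model([samples[i] for i in train])
        errors = []
        for i in hold:
            pred = predict(model, samples[i].triplet)
            if not np.isfinite(pred.pge2_pct):
                continue
            errors.append(pred.as_array() - samples[i].true_composition.as_array())
        if not errors:
            raise ValueError("degenerate split: no predictable holdout samples")
        per_iter[it] = np.sqrt(np.mean(np.square(errors), axis=0))
    mean_rmse = per_iter.mean(axis=0)
    return CVResult(
        rmse_pge2=float(mean_rmse[0]),
        rmse_pgd2=float(mean_rmse[1]),
        rmse_d12=float(mean_rmse[2]),
        n_iterations=n_iterations,
        holdout_fraction=holdout_fraction,
        seed=seed,
    )
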