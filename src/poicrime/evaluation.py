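"""Cross-validation designs, R^2 scoring, sweeps and summary arithmetic.

Two validation designs are provided.  Within a city, points (POIs of
each class, and crimes, independently) are split uniformly at random
into K near-equal parts (K = 2 by default, so each half still supports a
reliable density estimate), the model is fitted on training-half
densities and scored on test-half densities over the regular grid, and
the whole procedure is repeated (100 times by default) with fresh
splits.  Across cities, a combined model is fitted on the stacked
flattened rasters of all-but-one city (class columns aligned by name,
absent classes contributing zero columns) and scored on the held-out
city.

Because a 1/K sample of points carries 1/K of the intensity mass, each
split's density raster is multiplied by the inverse of its sampling
fraction so train and test densities are both on the full-data
incidents-per-km^2 scale (disable with ``strict_paper`` for raw,
uncompensated rasters).
"""

from __future__ import annotations

import logging
import zlib
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geodata_io import PointSet, StudyArea, window_points
from .density_estimation import (BasisMatrix, KernelSpec, build_basis,
                                 estimate_density)
from .sparse_model import (DEFAULT_ALCOHOL_CLASSES, ModelFit, baseline_fit,
                           lasso_fit, ols_refit, select_alpha_for_support)

logger = logging.getLogger(__name__)

__all__ = [
    "CvConfig",
    "CvResult",
    "CityBundle",
    "split_points",
    "r2_density",
    "cross_validate_city",
    "leave_one_city_out",
    "alpha_sweep",
    "kernel_sweep",
    "bandwidth_sweep",
    "count_selected_classes",
    "improvement_stats",
    "ImprovementStats",
    "displacement_summary",
    "DisplacementSummary",
]


@dataclass(frozen=True)
class CvConfig:
    """Repeated K-fold point-splitting design (defaults: K=2, 100 repeats)."""

    K: int = 2
    n_repeats: int = 100
    seed: int = 0
    k_select: int = 10

    def __post_init__(self):
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class CvResult:
    per_run_r2: list[float]
    mean_r2: float
    sd_r2: float
    per_run_selected: list[list[str]]

    @classmethod
    def from_runs(cls, r2s, selected):
        arr = np.asarray(r2s, dtype=float)
        return cls(list(map(float, arr)), float(arr.mean()),
                   float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
                   [list(s) for s in selected])


@dataclass
class CityBundle:
    """All inputs for one city: per-class POI sets, crimes, study area."""

    city_name: str
    class_sets: list[PointSet]
    crimes: PointSet
    area: StudyArea

    def __post_init__(self):
        names = [ps.label for ps in self.class_sets]
        if len(names) != len(set(names)):
            raise ValueError(f"duplicate class names in bundle {self.city_name!r}")


def split_points(sets: list[PointSet], K: int, seed: int,
                 ) -> list[list[PointSet]]:
    """Partition every point set independently into K near-equal parts.

    Returns, per input set, a list of K PointSets whose sizes differ by
    at most one and whose union restores the input.  Deterministic per
    seed.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    out = []
    for ps in sets:
        # per-set substream keyed by the class label, so the partition of
        # each class is independent of the ordering of the input list
        key = zlib.crc32(ps.label.encode())
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC5, key]))
        perm = rng.permutation(len(ps))
        parts = np.array_split(perm, K)
        out.append([PointSet(ps.label, ps.points[idx]) for idx in parts])
    return out


def r2_density(predicted, observed) -> float:
    """Coefficient of determination between flattened density rasters."""
    p = np.asarray(predicted, dtype=float).ravel()
    o = np.asarray(observed, dtype=float).ravel()
    if p.shape != o.shape:
        raise ValueError("length mismatch")
    ss_tot = float(((o - o.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("observed density has zero variance")
    return 1.0 - float(((o - p) ** 2).sum()) / ss_tot


def _alcohol_column(basis: BasisMatrix, alcohol_classes) -> np.ndarray:
    present = [c for c in alcohol_classes if c in basis.columns]
    if not present:
        raise ValueError(f"none of the alcohol classes {tuple(alcohol_classes)} "
                         "are in the basis")
    return sum(basis.column(c) for c in present)


def _windowed_bundle(bundle: CityBundle, kernel: KernelSpec) -> CityBundle:
    pad = kernel.bandwidth
    return CityBundle(
        bundle.city_name,
        [window_points(ps, bundle.area, pad) for ps in bundle.class_sets],
        window_points(bundle.crimes, bundle.area, pad),
        bundle.area,
    )


def _fold_density_inputs(bundle, kernel, cfg, repeat, strict_paper):
    """Yield per-fold (train_basis, train_y, test_basis, test_y) tuples."""
    K = cfg.K
    seed = int(np.random.SeedSequence([cfg.seed, repeat]).generate_state(1)[0]
               % (2 ** 31))
    parts = split_points(bundle.class_sets + [bundle.crimes], K, seed)
    class_parts, crime_parts = parts[:-1], parts[-1]
    train_scale = 1.0 if strict_paper else K / (K - 1)
    test_scale = 1.0 if strict_paper else float(K)
    for f in range(K):
        train_sets = [
            PointSet(pp[0].label,
                     np.vstack([pp[j].points for j in range(K) if j != f]))
            for pp in class_parts
        ]
        test_sets = [pp[f] for pp in class_parts]
        train_crimes = PointSet("crime", np.vstack(
            [crime_parts[j].points for j in range(K) if j != f]))
        test_crimes = crime_parts[f]
        for ps in train_sets:
            if len(ps) == 0:
                logger.warning("class %r empty in training split", ps.label)
        train_basis = build_basis(train_sets, bundle.area, kernel, train_scale)
        test_basis = build_basis(test_sets, bundle.area, kernel, test_scale)
        train_y = estimate_density(train_crimes, bundle.area, kernel,
                                   train_scale).flatten()
        test_y = estimate_density(test_crimes, bundle.area, kernel,
                                  test_scale).flatten()
        yield train_basis, train_y, test_basis, test_y


def cross_validate_city(bundle: CityBundle, cfg: CvConfig, kernel: KernelSpec,
                        alcohol_classes=DEFAULT_ALCOHOL_CLASSES,
                        strict_paper: bool = False,
                        ) -> tuple[CvResult, CvResult]:
    """Repeated K-fold point-split CV of the sparse model and the baseline.

    Returns (proposed, baseline) CvResults with K * n_repeats runs each.
    """
    bundle = _windowed_bundle(bundle, kernel)
    prop_r2, prop_sel, base_r2 = [], [], []
    for rep in range(cfg.n_repeats):
        for tb, ty, sb, sy in _fold_density_inputs(bundle, kernel, cfg, rep,
                                                   strict_paper):
            sel = select_alpha_for_support(tb, ty, k=cfg.k_select)
            fit = ols_refit(tb, sel.selected_classes, ty, sel.alpha)
            prop_r2.append(r2_density(fit.predict(sb), sy))
            prop_sel.append(sel.selected_classes)

            bx = _alcohol_column(tb, alcohol_classes)
            bfit = baseline_fit(bx, ty, class_name="alcohol")
            pred = bfit.intercept + bfit.ols_coefficients["alcohol"] * \
                _alcohol_column(sb, alcohol_classes)
            base_r2.append(r2_density(pred, sy))
    return (CvResult.from_runs(prop_r2, prop_sel),
            CvResult.from_runs(base_r2, [["alcohol"]] * len(base_r2)))


def _full_city_arrays(bundle: CityBundle, kernel: KernelSpec, vocab):
    """Basis (aligned to vocab, zero columns for absent classes) and crime y."""
    wb = _windowed_bundle(bundle, kernel)
    present = {ps.label: ps for ps in wb.class_sets}
    sets = [present.get(name, PointSet(name)) for name in vocab]
    basis = build_basis(sets, wb.area, kernel)
    y = estimate_density(wb.crimes, wb.area, kernel).flatten()
    return basis, y


def leave_one_city_out(bundles: list[CityBundle], cfg: CvConfig,
                       kernel: KernelSpec) -> tuple[pd.DataFrame, list[ModelFit]]:
    """Combined-model CV: train on all-but-one city, score on the holdout.

    Class columns are aligned by name across cities (sorted union
    vocabulary); a class absent from a city contributes a zero column
    for that city's rows.  Returns the per-city R^2 table and the fits.
    """
    if len(bundles) < 2:
        raise ValueError("need at least two cities")
    vocab = sorted({ps.label for b in bundles for ps in b.class_sets})
    if not vocab:
        raise ValueError("empty class vocabulary")
    arrays = [_full_city_arrays(b, kernel, vocab) for b in bundles]

    rows, fits = [], []
    for i, held in enumerate(bundles):
        train_B = np.vstack([arrays[j][0].matrix
                             for j in range(len(bundles)) if j != i])
        train_y = np.concatenate([arrays[j][1]
                                  for j in range(len(bundles)) if j != i])
        basis = pd.DataFrame(train_B, columns=vocab)
        sel = select_alpha_for_support(basis, train_y, k=cfg.k_select)
        fit = ols_refit(basis, sel.selected_classes, train_y, sel.alpha)
        held_B, held_y = arrays[i]
        rows.append({"city": held.city_name,
                     "r2": r2_density(fit.predict(held_B), held_y)})
        fits.append(fit)
    return pd.DataFrame(rows), fits


def alpha_sweep(bundle: CityBundle, alphas, cfg: CvConfig, kernel: KernelSpec,
                strict_paper: bool = False) -> pd.DataFrame:
    """Mean test R^2 and mean support size across an alpha list under CV."""
    bundle = _windowed_bundle(bundle, kernel)
    records = {a: {"r2": [], "support": []} for a in alphas}
    for rep in range(cfg.n_repeats):
        for tb, ty, sb, sy in _fold_density_inputs(bundle, kernel, cfg, rep,
                                                   strict_paper):
            for a in alphas:
                fit = lasso_fit(tb, ty, a)
                support = fit.support
                records[a]["support"].append(len(support))
                if support:
                    refit = ols_refit(tb, support, ty, a)
                    pred = refit.predict(sb)
                else:
                    pred = np.full_like(sy, ty.mean())  # intercept-only
                records[a]["r2"].append(r2_density(pred, sy))
    return pd.DataFrame([
        {"alpha": a, "mean_r2": float(np.mean(v["r2"])),
         "mean_support": float(np.mean(v["support"]))}
        for a, v in records.items()
    ])


def kernel_sweep(bundle: CityBundle, kinds, cfg: CvConfig, bandwidth: float,
                 alcohol_classes=DEFAULT_ALCOHOL_CLASSES) -> pd.DataFrame:
    """CV performance per kernel family at fixed bandwidth, best first."""
    rows = []
    for kind in kinds:
        prop, _ = cross_validate_city(bundle, cfg, KernelSpec(kind, bandwidth),
                                      alcohol_classes)
        rows.append({"kernel": kind, "mean_r2": prop.mean_r2,
                     "sd_r2": prop.sd_r2})
    return (pd.DataFrame(rows).sort_values("mean_r2", ascending=False)
            .reset_index(drop=True))


def bandwidth_sweep(bundle: CityBundle, bandwidths, cfg: CvConfig,
                    kind: str = "exponential",
                    alcohol_classes=DEFAULT_ALCOHOL_CLASSES) -> pd.DataFrame:
    """CV performance across bandwidths.  Larger bandwidths tend to score
    higher while reducing the spatial resolution of the prediction; the
    choice is use-case dependent."""
    rows = []
    for h in bandwidths:
        prop, _ = cross_validate_city(bundle, cfg, KernelSpec(kind, float(h)),
                                      alcohol_classes)
        rows.append({"bandwidth": float(h), "mean_r2": prop.mean_r2,
                     "sd_r2": prop.sd_r2})
    return pd.DataFrame(rows)


def count_selected_classes(city_fits: list[ModelFit]) -> pd.DataFrame:
    """How many city models selected each class (descending, ties A-Z)."""
    counts = Counter()
    for fit in city_fits:
        counts.update(set(fit.selected_classes))
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(rows, columns=["class", "count"])


@dataclass
class ImprovementStats:
    per_city: dict[str, int]
    mean: float
    mean_excluding: float
    excluded: tuple[str, ...]


def improvement_stats(baseline_means, model_means, city_names,
                      exclude=()) -> ImprovementStats:
    """Per-city percentage improvement of the model over the baseline.

    Each city's improvement is 100*(model - baseline)/baseline truncated
    to an integer percent; the overall mean of those integers is
    reported to one decimal, with a variant excluding the named outlier
    cities.
    """
    b = np.asarray(baseline_means, dtype=float)
    m = np.asarray(model_means, dtype=float)
    if not (len(b) == len(m) == len(city_names)):
        raise ValueError("length mismatch")
    if np.any(b <= 0):
        raise ValueError("baseline means must be positive")
    pct = np.trunc(100.0 * (m - b) / b).astype(int)
    per_city = {c: int(p) for c, p in zip(city_names, pct)}
    kept = [per_city[c] for c in city_names if c not in set(exclude)]
    return ImprovementStats(
        per_city=per_city,
        mean=round(float(np.mean(pct)), 1),
        mean_excluding=round(float(np.mean(kept)), 1) if kept else float("nan"),
        excluded=tuple(exclude),
    )


@dataclass
class DisplacementSummary:
    mean: float
    median: float       # mid-average convention for even counts
    p90: float          # nearest-rank percentile
    bin_edges: np.ndarray
    bin_counts: np.ndarray


def displacement_summary(displacements, bin_width: float = 5.0,
                         ) -> DisplacementSummary:
    """Quantisation-noise summary of anonymisation displacement distances."""
    d = np.sort(np.asarray(displacements, dtype=float).ravel())
    if d.size == 0:
        raise ValueError("no displacements")
    rank = max(int(np.ceil(0.9 * d.size)), 1)
    p90 = float(d[rank - 1])
    top = max(float(d.max()), bin_width)
    edges = np.arange(0.0, np.ceil(top / bin_width) * bin_width + bin_width,
                      bin_width)
    counts, _ = np.histogram(d, bins=edges)
    return DisplacementSummary(mean=float(d.mean()), median=float(np.median(d)),
                               p90=p90, bin_edges=edges, bin_counts=counts)
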