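"""Decision-level fusion and the cross-validated evaluation harness.

The fused classifier combines the low-frequency ERP route (DCPM on
delta-filtered 500-850 ms data) with the high-frequency power route (CSP on
20-60 Hz-filtered 100-800 ms data) of the *same* trials: each route's
Fisher read-out yields a scalar decision value and the fused label is
``sign(F1 + F2)`` (+1 = T400, -1 = T600; an exact zero resolves to +1).

Cross-validation is stratified k-fold with seeded shuffling.  Every model
component — templates, DSP filters, per-trial CCA read-outs, CSP filter
banks, and both FDA read-outs — is refit strictly on each training fold.
Fold assignment depends only on the labels and the seed, never on the data
values, so paired comparisons across bands or methods share folds.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .core import BANDS, BandSpec, EpochSet, WindowSpec, select
from .csp import csp_fit, csp_predict
from .dcpm import dcpm_fit, dcpm_predict
from .fda import FdaModel, fda_fit  # noqa: F401  (re-exported harness surface)
from .preprocess import FilterSpec, baseline_correct, zero_phase_filter

__all__ = [
    "DCPM_BAND", "DCPM_WINDOW", "CSP_BAND", "CSP_WINDOW", "BASELINE_WINDOW",
    "FdaModel", "fda_fit", "fuse_decision", "CvResult",
    "cross_validate", "band_sweep", "compare_methods", "results_to_frame",
]

#: Defaults of the fused pipeline: delta-band ERPs for DCPM, the combined
#: beta + mid-gamma band for CSP.
DCPM_BAND = BANDS["delta"]
DCPM_WINDOW = WindowSpec(500.0, 850.0)
CSP_BAND = BANDS["high"]
CSP_WINDOW = WindowSpec(100.0, 800.0)
BASELINE_WINDOW = WindowSpec(-100.0, 0.0)


def fuse_decision(f1: float, f2: float) -> int:
    """Fused label from the two decision values: ``sign(F1 + F2)``."""
    if not (np.isfinite(f1) and np.isfinite(f2)):
        raise ValueError(f"non-finite decision values: F1={f1}, F2={f2}")
    return 1 if f1 + f2 >= 0 else -1


@dataclass
class CvResult:
    """Cross-validation outcome with full provenance."""

    method: str
    band: str
    per_fold_acc: list[float]
    mean_acc: float
    n_folds: int
    seed: int
    config_digest: str

    def __post_init__(self) -> None:
        if not all(0 <= a <= 1 for a in self.per_fold_acc):
            raise ValueError("per-fold accuracies must lie in [0, 1]")


def _digest(**kwargs) -> str:
    blob = json.dumps({k: repr(v) for k, v in sorted(kwargs.items())})
    return hashlib.md5(blob.encode()).hexdigest()[:12]


def _prepare(epochs: EpochSet, band: BandSpec | None, window: WindowSpec,
             baseline: WindowSpec | None) -> EpochSet:
    """Band-filter, baseline-correct, then cut the analysis window."""
    out = epochs
    if band is not None:
        out = zero_phase_filter(out, FilterSpec.from_band(band))
    if baseline is not None:
        out = baseline_correct(out, baseline)
    return select(out, window=window)


def _folds(labels: np.ndarray, k: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    counts = [int(np.sum(labels == c)) for c in (1, -1)]
    if min(counts) < k:
        raise ValueError(
            f"stratified {k}-fold needs at least {k} trials per class, "
            f"got {counts}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(labels)), labels))


def _run_folds(prepared: dict[str, EpochSet], labels: np.ndarray,
               folds: list, method: str,
               n_components: int | None) -> list[tuple[int, int]]:
    """Per fold: (n_correct, n_test)."""
    out = []
    for train_idx, test_idx in folds:
        y_test = labels[test_idx]
        if method in ("dcpm", "fusion"):
            m1 = dcpm_fit(prepared["dcpm"].take(train_idx), n_components)
            pred1, f1 = dcpm_predict(m1, prepared["dcpm"].take(test_idx))
        if method in ("csp", "fusion"):
            m2 = csp_fit(prepared["csp"].take(train_idx))
            pred2, f2 = csp_predict(m2, prepared["csp"].take(test_idx))
        if method == "dcpm":
            pred = pred1
        elif method == "csp":
            pred = pred2
        else:
            pred = np.array([fuse_decision(a, b) for a, b in zip(f1, f2)])
        out.append((int(np.sum(pred == y_test)), len(y_test)))
    return out


def cross_validate(epochs: EpochSet, method: str, *,
                   bands: dict[str, BandSpec] | None = None,
                   windows: dict[str, WindowSpec] | None = None,
                   k: int = 10, seed: int = 0,
                   baseline: WindowSpec | None = BASELINE_WINDOW,
                   n_components: int | None = None) -> CvResult:
    """Stratified k-fold accuracy of one method on one subject's epochs.

    ``bands``/``windows`` override the per-route defaults, keyed by
    ``'dcpm'`` and/or ``'csp'``.  Trials with labels other than +1/-1 are
    ignored.  The mean accuracy weights folds by their size.
    """
    if method not in ("dcpm", "csp", "fusion"):
        raise ValueError(f"unknown method {method!r}")
    two_class = select(epochs, labels=[1, -1])
    band_map = {"dcpm": DCPM_BAND, "csp": CSP_BAND}
    win_map = {"dcpm": DCPM_WINDOW, "csp": CSP_WINDOW}
    if bands:
        band_map.update(bands)
    if windows:
        win_map.update(windows)

    prepared = {}
    for route in ("dcpm", "csp"):
        if method in (route, "fusion"):
            prepared[route] = _prepare(two_class, band_map[route],
                                       win_map[route], baseline)
    folds = _folds(two_class.labels, k, seed)
    counts = _run_folds(prepared, two_class.labels, folds, method, n_components)

    per_fold = [c / n for c, n in counts]
    mean_acc = sum(c for c, _ in counts) / sum(n for _, n in counts)
    band_desc = "+".join(sorted({band_map[r].name for r in prepared}))
    digest = _digest(method=method, bands={r: band_map[r] for r in prepared},
                     windows={r: win_map[r] for r in prepared}, k=k, seed=seed,
                     baseline=baseline, n_components=n_components)
    return CvResult(method=method, band=band_desc, per_fold_acc=per_fold,
                    mean_acc=float(mean_acc), n_folds=k, seed=seed,
                    config_digest=digest)


def band_sweep(epochs: EpochSet, method: str, bands: list[BandSpec], *,
               k: int = 10, seed: int = 0,
               baseline: WindowSpec | None = BASELINE_WINDOW,
               n_components: int | None = None) -> list[CvResult]:
    """One CvResult per band with identical folds (paired comparison).

    The method's analysis window stays at its default; only the filter
    band changes, as in a band-wise sweep of classification accuracy.
    """
    if method not in ("dcpm", "csp"):
        raise ValueError("band_sweep supports the single methods 'dcpm' and 'csp'")
    return [
        cross_validate(epochs, method, bands={method: band}, k=k, seed=seed,
                       baseline=baseline, n_components=n_components)
        for band in bands
    ]


def results_to_frame(results: list[CvResult]) -> pd.DataFrame:
    """Tabular view: one row per result, per-fold accuracies as columns."""
    rows = []
    for r in results:
        row = {"method": r.method, "band": r.band, "mean_acc": r.mean_acc,
               "n_folds": r.n_folds, "seed": r.seed,
               "config_digest": r.config_digest}
        row.update({f"fold{i}": a for i, a in enumerate(r.per_fold_acc)})
        rows.append(row)
    return pd.DataFrame(rows)


def compare_methods(cohort: list[EpochSet], *, k: int = 10,
                    seed: int = 0) -> pd.DataFrame:
    """Per-subject accuracy (percent) of DCPM, CSP, and the fusion.

    Columns mirror the three-method comparison table: one row per subject
    plus Mean and Std summary rows.  Within a subject all three methods
    share folds; fold shuffling differs across subjects.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    rows = []
    for i, epochs in enumerate(cohort):
        sub_seed = (seed + i) % (2**31)
        accs = {
            method: 100.0 * cross_validate(epochs, method, k=k,
                                           seed=sub_seed).mean_acc
            for method in ("dcpm", "csp", "fusion")
        }
        rows.append({"subject": str(i + 1), **accs})
    df = pd.DataFrame(rows)
    summary = pd.DataFrame([
        {"subject": "Mean", **{m: df[m].mean() for m in ("dcpm", "csp", "fusion")}},
        {"subject": "Std", **{m: (df[m].std(ddof=1) if len(df) > 1 else 0.0)
                              for m in ("dcpm", "csp", "fusion")}},
    ])
    return pd.concat([df, summary], ignore_index=True)
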