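"""F1 scoring, best-channel selection and the full factorial grid.

The factorial design crosses, per subject,

* 5 frequency bands ([0.01-1] ... [4-5] Hz),
* 5 spatial representations with 19 (NoF) + 9 (SL) + 19 (ICA) + 19 (PCA)
  + 1 (CSP) = 67 candidate channels/components,
* 6 detectors,

for 5 x 67 x 6 = 2,010 combinations per subject.  For each (band, spatial
method, detector) cell the channel/component with the highest test-set F1
is retained, giving the 5 x 5 x 6 = 150-cell table that feeds the
repeated-measures ANOVA.

Performance is summarized exclusively by the F1 score
``F1 = 2 / (recall^-1 + precision^-1)`` with the MRCP class as positive;
``F1 = 0`` when there are no true positives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import detect, preprocess, spatial
from .montage import Montage, default_montage
from .preprocess import ANALYSIS_BANDS, MRCP, BandSpec, Epoch
from .synth import Session

__all__ = [
    "GridConfig",
    "F1Result",
    "FactorialResult",
    "f1_from_counts",
    "score_predictions",
    "select_best_channel",
    "run_grid",
    "channel_f1_map",
    "planned_cells",
]

logger = logging.getLogger(__name__)


def f1_from_counts(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """(precision, recall, F1) from confusion counts; F1 = 0 when tp = 0."""
    if tp + fp + fn < 1:
        raise ValueError("need at least one positive or predicted-positive sample")
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if tp > 0 else 0.0
    return precision, recall, f1


@dataclass
class F1Result:
    subject_id: str
    band: str
    spatial_method: str
    channel_index: int
    channel_name: str
    classifier: str
    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    f1: float


def score_predictions(
    y_true: np.ndarray, y_pred: np.ndarray, **ids
) -> F1Result:
    """Confusion counts + F1 for 0/1 label vectors (1 = MRCP)."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    fp = int(np.sum((y_pred == 1) & (y_true == 0)))
    fn = int(np.sum((y_pred == 0) & (y_true == 1)))
    tn = int(np.sum((y_pred == 0) & (y_true == 0)))
    precision, recall, f1 = f1_from_counts(tp, fp, fn)
    defaults = dict(
        subject_id="S0", band="", spatial_method="", channel_index=0,
        channel_name="", classifier="",
    )
    defaults.update(ids)
    return F1Result(tp=tp, fp=fp, fn=fn, tn=tn, precision=precision,
                    recall=recall, f1=f1, **defaults)


def select_best_channel(results: Sequence[F1Result]) -> F1Result:
    """Argmax of F1; ties go to the first (lowest channel index) entry."""
    if not results:
        raise ValueError("no channel results to select from")
    best = results[0]
    for r in results[1:]:
        if r.f1 > best.f1:
            best = r
    return best


@dataclass
class GridConfig:
    """What to run: factor levels, seeds, and desk-scale knobs."""

    bands: list[BandSpec] = field(default_factory=lambda: list(ANALYSIS_BANDS))
    spatial_methods: list[str] = field(default_factory=lambda: list(spatial.SPATIAL_METHODS))
    classifiers: list[str] = field(default_factory=lambda: list(detect.DETECTORS))
    seed: int = 0
    decimate_to: float | None = 64.0
    montage: Montage | None = None
    split_ratio: tuple[float, float] = (2 / 3, 1 / 3)
    use_ground_truth_events: bool = True
    test_set_thresholds: bool = False  # optimistic variant: calibrate MF/TM on test


@dataclass
class FactorialResult:
    """Tidy per-channel grid + the per-cell best-channel table."""

    grid: pd.DataFrame
    best: pd.DataFrame
    missing: list[dict] = field(default_factory=list)


def planned_cells(cfg: GridConfig, n_channels: int = 19, n_sl: int = 9) -> int:
    per_band = sum(spatial.n_outputs(m, n_channels, n_sl) for m in cfg.spatial_methods)
    return len(cfg.bands) * per_band * len(cfg.classifiers)


def _cell_seed(root: int, *keys: int) -> int:
    return int(np.random.SeedSequence([root, *keys]).generate_state(1)[0] % 2**31)


def _prepare_band(
    session: Session, band: BandSpec, cfg: GridConfig, split_seed: int
) -> tuple[list[Epoch], list[Epoch]]:
    """Filter -> segment -> split -> decimate.

    Epochs stay *unnormalized* here: spatial filters must see the true
    relative channel amplitudes (per-channel normalization before a
    surface Laplacian would equalize the channels and cancel the very
    topography the filter is meant to exploit).  Each single-channel
    spatial output is z-normalized later, just before detection.
    """
    cascade = band.lo < 0.1 and session.fs > 512  # near-singular narrow band edge
    filtered = preprocess.bandpass(session, band, cascade=cascade)
    epochs = preprocess.segment(filtered)
    for ep in epochs:
        ep.band = band
    split = preprocess.stratified_split(epochs, cfg.split_ratio, seed=split_seed)
    train, test = split.train, split.test
    if cfg.decimate_to and cfg.decimate_to != session.fs:
        train = preprocess.decimate_epochs(train, cfg.decimate_to)
        test = preprocess.decimate_epochs(test, cfg.decimate_to)
    return train, test


def run_grid(sessions: Sequence[Session], cfg: GridConfig | None = None) -> FactorialResult:
    """Execute the factorial study on a cohort of sessions.

    Per subject and band: band-pass, segment, z-normalize and split; fit
    each spatial model on the training epochs only; then, for every output
    channel/component and detector, fit on train and score F1 on test.
    Deterministic for fixed ``cfg.seed``.  Degenerate cells are recorded in
    ``missing`` with their reason, never silently dropped.
    """
    cfg = cfg or GridConfig()
    montage = cfg.montage or default_montage()
    rows: list[F1Result] = []
    missing: list[dict] = []
    for si, session in enumerate(sessions):
        events = session.events if cfg.use_ground_truth_events else session.ground_truth
        if not events:
            raise ValueError(f"session {session.subject_id} has no events")
        for bi, band in enumerate(cfg.bands):
            split_seed = _cell_seed(cfg.seed, si, bi)
            train, test = _prepare_band(session, band, cfg, split_seed)
            for mi, method in enumerate(cfg.spatial_methods):
                sp_seed = _cell_seed(cfg.seed, si, bi, mi)
                model = spatial.fit_spatial(method, train, montage, seed=sp_seed)
                train_out = [spatial.apply_spatial(model, ep) for ep in train]
                test_out = [spatial.apply_spatial(model, ep) for ep in test]
                for ci in range(model.n_outputs):
                    tr = preprocess.znormalize_all([outs[ci] for outs in train_out])
                    te = preprocess.znormalize_all([outs[ci] for outs in test_out])
                    y_test = np.array([1 if ep.label == MRCP else 0 for ep in te])
                    for ki, clf in enumerate(cfg.classifiers):
                        ids = dict(
                            subject_id=session.subject_id,
                            band=band.name,
                            spatial_method=method,
                            channel_index=ci,
                            channel_name=model.output_names[ci],
                            classifier=clf,
                        )
                        try:
                            det_seed = _cell_seed(cfg.seed, si, bi, mi, ci, ki)
                            fit_on = tr + te if cfg.test_set_thresholds and clf in ("MF", "TM") else tr
                            det = detect.fit_detector(clf, fit_on, seed=det_seed)
                            y_pred = detect.predict_batch(det, te)
                            rows.append(score_predictions(y_test, y_pred, **ids))
                        except Exception as exc:  # degenerate cell
                            logger.warning("missing cell %s: %s", ids, exc)
                            missing.append({**ids, "reason": str(exc)})
    grid = pd.DataFrame([vars(r) for r in rows])
    best_rows = []
    if not grid.empty:
        for (subj, band_name, method, clf), sub in grid.groupby(
            ["subject_id", "band", "spatial_method", "classifier"], sort=False
        ):
            res = [F1Result(**rec) for rec in sub.to_dict("records")]
            best_rows.append(vars(select_best_channel(res)))
    best = pd.DataFrame(best_rows)
    return FactorialResult(grid=grid, best=best, missing=missing)


def channel_f1_map(
    session: Session,
    band: BandSpec | None = None,
    classifier: str = "LDA",
    cfg: GridConfig | None = None,
) -> pd.DataFrame:
    """Per-channel F1 of the surface-Laplacian representation in one band.

    Returns one row per working SL electrode (channel, f1, precision,
    recall), the tabular analogue of a topographic F1 map.  Defaults to
    the [0.01-1] Hz band, where the MRCP negativity is strongest.
    """
    band = band or ANALYSIS_BANDS[0]
    cfg = cfg or GridConfig()
    cfg = GridConfig(**{**vars(cfg), "bands": [band], "spatial_methods": ["SL"],
                        "classifiers": [classifier]})
    result = run_grid([session], cfg)
    out = result.grid[["channel_name", "f1", "precision", "recall"]].copy()
    out["channel"] = out["channel_name"].str.replace("SL-", "", regex=False)
    return out[["channel", "f1", "precision", "recall"]].reset_index(drop=True)
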