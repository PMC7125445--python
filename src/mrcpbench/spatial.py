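"""Spatial representations of multichannel epochs.

Five backends, each mapping a multichannel epoch to a set of candidate
single-channel representations:

==========  ===========================================  =========
method      transform                                    outputs
==========  ===========================================  =========
``NoF``     identity (raw channels)                      19
``SL``      surface Laplacian at the 9 interior sites    9
``ICA``     FastICA unmixing fitted on training data     19
``CSP``     best common-spatial-pattern filter           1
``PCA``     principal-component projection               19
==========  ===========================================  =========

The surface Laplacian subtracts the mean of a channel's montage
neighbours from the channel itself (all neighbour distances treated as
equal), acting as a spatial high-pass that suppresses common-mode
activity.  CSP solves the two-class generalized eigenproblem of the
class-average covariance matrices and keeps the single filter that
maximizes the MRCP / non-MRCP variance ratio.  ICA and PCA are fitted on
the concatenation of all *training* epochs only and then applied epoch by
epoch, so no test-set information reaches the fit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import linalg
from sklearn.decomposition import PCA, FastICA
from sklearn.exceptions import ConvergenceWarning

from .montage import Montage, default_montage
from .preprocess import MRCP, NON_MRCP, Epoch

__all__ = ["SPATIAL_METHODS", "SpatialModel", "fit_spatial", "apply_spatial", "n_outputs"]

SPATIAL_METHODS = ["NoF", "SL", "ICA", "CSP", "PCA"]


@dataclass
class SpatialModel:
    """A fitted spatial transform: outputs = weights @ (epoch - mean)."""

    method: str
    weights: np.ndarray        # (n_outputs, n_channels)
    output_names: list[str]
    channel_names: list[str]
    mean: np.ndarray | None = None  # per-channel offset removed before projection
    fit_metadata: dict = field(default_factory=dict)

    @property
    def n_outputs(self) -> int:
        return self.weights.shape[0]

    def to_json(self, path: str | Path) -> None:
        """Serialize the fitted transform (weights, names, metadata) to JSON."""
        payload = {
            "method": self.method,
            "weights": self.weights.tolist(),
            "output_names": self.output_names,
            "channel_names": self.channel_names,
            "mean": None if self.mean is None else self.mean.tolist(),
            "fit_metadata": self.fit_metadata,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "SpatialModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            method=payload["method"],
            weights=np.array(payload["weights"]),
            output_names=list(payload["output_names"]),
            channel_names=list(payload["channel_names"]),
            mean=None if payload["mean"] is None else np.array(payload["mean"]),
            fit_metadata=dict(payload["fit_metadata"]),
        )


def n_outputs(method: str, n_channels: int = 19, n_sl: int = 9) -> int:
    return {"NoF": n_channels, "SL": n_sl, "ICA": n_channels, "CSP": 1, "PCA": n_channels}[
        method
    ]


def _normalize_signs(w: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude element of each filter positive (reproducibility)."""
    w = w.copy()
    for row in w:
        k = np.argmax(np.abs(row))
        if row[k] < 0:
            row *= -1.0
    return w


def _concat_train(train_epochs: Sequence[Epoch]) -> np.ndarray:
    """Concatenate training epochs along time -> (n_channels, total_samples)."""
    return np.concatenate([ep.data for ep in train_epochs], axis=1)


def _sl_weights(montage: Montage) -> tuple[np.ndarray, list[str]]:
    n = len(montage.channel_names)
    rows = []
    names = []
    for ch in montage.working_sl_channels:
        w = np.zeros(n)
        w[montage.index(ch)] = 1.0
        nbrs = sorted(montage.neighbors[ch])
        for nb in nbrs:
            w[montage.index(nb)] = -1.0 / len(nbrs)
        rows.append(w)
        names.append(f"SL-{ch}")
    return np.array(rows), names


def _fit_csp(
    train_epochs: Sequence[Epoch], ridge: float = 1e-6, favor: str = MRCP
) -> np.ndarray:
    """One CSP filter maximizing the variance ratio in favour of ``favor``."""
    covs = {MRCP: [], NON_MRCP: []}
    for ep in train_epochs:
        x = ep.data
        covs[ep.label].append(x @ x.T / x.shape[1])
    if not covs[MRCP] or not covs[NON_MRCP]:
        raise ValueError("CSP requires training epochs of both classes")
    c1 = np.mean(covs[MRCP], axis=0)
    c2 = np.mean(covs[NON_MRCP], axis=0)
    n = c1.shape[0]
    c1 = c1 + ridge * np.trace(c1) / n * np.eye(n)
    c2 = c2 + ridge * np.trace(c2) / n * np.eye(n)
    evals, evecs = linalg.eigh(c1, c1 + c2)
    w = evecs[:, -1] if favor == MRCP else evecs[:, 0]
    return w[None, :]


def fit_spatial(
    method: str,
    train_epochs: Sequence[Epoch],
    montage: Montage | None = None,
    seed: int = 0,
    ica_max_retries: int = 3,
) -> SpatialModel:
    """Fit a spatial transform on training epochs only.

    ``NoF`` and ``SL`` need no fitting (identity / fixed montage weights);
    ``ICA``/``PCA`` are estimated on the concatenation of all training
    epochs; ``CSP`` on the two class-average covariances.  FastICA
    non-convergence is retried with fresh seeds up to ``ica_max_retries``
    times and flagged in ``fit_metadata['converged']``.
    """
    if method not in SPATIAL_METHODS:
        raise ValueError(f"unknown spatial method {method!r}")
    montage = montage or default_montage()
    names = list(montage.channel_names)
    if train_epochs and list(train_epochs[0].channel_names) != names:
        raise ValueError("epoch channel order does not match montage")
    meta: dict = {"seed": seed}

    if method == "NoF":
        w = np.eye(len(names))
        return SpatialModel(method, w, list(names), names, fit_metadata=meta)
    if method == "SL":
        w, out_names = _sl_weights(montage)
        return SpatialModel(method, w, out_names, names, fit_metadata=meta)
    if not train_epochs:
        raise ValueError(f"{method} requires training epochs")

    if method == "CSP":
        w = _normalize_signs(_fit_csp(train_epochs))
        return SpatialModel(method, w, ["CSP-1"], names, fit_metadata=meta)

    x = _concat_train(train_epochs).T  # (samples, channels)
    if method == "PCA":
        pca = PCA(n_components=len(names), svd_solver="full")
        pca.fit(x)
        w = _normalize_signs(pca.components_)
        out_names = [f"PC{i + 1}" for i in range(w.shape[0])]
        return SpatialModel(
            method, w, out_names, names, mean=pca.mean_, fit_metadata=meta
        )

    # ICA
    converged = False
    n_iter = 0
    for attempt in range(ica_max_retries + 1):
        ica = FastICA(
            n_components=len(names),
            algorithm="deflation",
            fun="logcosh",
            whiten="unit-variance",
            max_iter=500,
            random_state=seed + attempt,
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            ica.fit(x)
        n_iter = int(getattr(ica, "n_iter_", 0))
        converged = not any(issubclass(c.category, ConvergenceWarning) for c in caught)
        if converged:
            break
    meta.update({"converged": converged, "n_iter": n_iter, "attempts": attempt + 1})
    w = _normalize_signs(ica.components_)
    out_names = [f"IC{i + 1}" for i in range(w.shape[0])]
    return SpatialModel(method, w, out_names, names, mean=ica.mean_, fit_metadata=meta)


def apply_spatial(model: SpatialModel, epoch: Epoch) -> list[Epoch]:
    """Project one multichannel epoch to the model's single-channel outputs."""
    if list(epoch.channel_names) != list(model.channel_names):
        raise ValueError("epoch channel order does not match spatial model")
    x = epoch.data
    if model.mean is not None:
        x = x - model.mean[:, None]
    y = model.weights @ x
    out = []
    for i, name in enumerate(model.output_names):
        out.append(
            Epoch(
                data=y[i : i + 1],
                label=epoch.label,
                fs=epoch.fs,
                subject_id=epoch.subject_id,
                band=epoch.band,
                source_event=epoch.source_event,
                channel_names=[name],
            )
        )
    return out
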