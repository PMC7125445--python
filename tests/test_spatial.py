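"""Spatial transforms: Laplacian arithmetic, CSP/PCA/ICA recovery oracles."""

import numpy as np
import pytest

from mrcpbench.montage import Montage, default_montage
from mrcpbench.preprocess import MRCP, NON_MRCP, Epoch
from mrcpbench.spatial import (
    SPATIAL_METHODS,
    _fit_csp,
    apply_spatial,
    fit_spatial,
    n_outputs,
)


def _epoch_from_matrix(x, names, label=MRCP, fs=32.0):
    return Epoch(data=np.asarray(x, dtype=float), label=label, fs=fs,
                 channel_names=list(names))


def _toy_montage(n):
    names = tuple(f"ch{i}" for i in range(n))
    return Montage(channel_names=names,
                   neighbors={c: frozenset() for c in names},
                   working_sl_channels=())


@pytest.fixture(scope="module")
def montage():
    return default_montage()


@pytest.fixture(scope="module")
def train_19ch(montage):
    rng = np.random.default_rng(0)
    eps = []
    for i in range(8):
        label = MRCP if i % 2 == 0 else NON_MRCP
        x = rng.standard_normal((19, 64))
        if label == MRCP:
            x[montage.index("Cz")] += np.linspace(0, -3, 64)
        eps.append(_epoch_from_matrix(x, montage.channel_names, label))
    return eps


class TestSurfaceLaplacian:
    def test_common_mode_is_rejected(self, montage):
        x = np.tile(np.sin(np.linspace(0, 3, 40)), (19, 1))
        model = fit_spatial("SL", [], montage)
        outs = apply_spatial(model, _epoch_from_matrix(x, montage.channel_names))
        for out in outs:
            assert np.allclose(out.data, 0.0, atol=1e-12)

    def test_cz_surrogate_hand_value(self, montage):
        # Cz = 4, each of its four neighbours (Fz, C3, C4, Pz) = 1 -> 4 - 1 = 3
        x = np.zeros((19, 4))
        x[montage.index("Cz"), 2] = 4.0
        for nb in ["Fz", "C3", "C4", "Pz"]:
            x[montage.index(nb), 2] = 1.0
        model = fit_spatial("SL", [], montage)
        outs = apply_spatial(model, _epoch_from_matrix(x, montage.channel_names))
        cz_out = outs[model.output_names.index("SL-Cz")]
        assert cz_out.data[0, 2] == pytest.approx(3.0)

    def test_translation_invariance(self, montage):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((19, 30))
        model = fit_spatial("SL", [], montage)
        base = apply_spatial(model, _epoch_from_matrix(x, montage.channel_names))
        shifted = apply_spatial(model, _epoch_from_matrix(x + 7.5, montage.channel_names))
        for a, b in zip(base, shifted):
            assert np.allclose(a.data, b.data, atol=1e-10)


class TestCSP:
    @staticmethod
    def _two_class_toy(seed=0, n=40, t=200):
        rng = np.random.default_rng(seed)
        eps = []
        for _ in range(n):
            a = np.vstack([3.0 * rng.standard_normal(t), 0.3 * rng.standard_normal(t)])
            eps.append(Epoch(data=a, label=MRCP, fs=100.0, channel_names=["ch0", "ch1"]))
            b = np.vstack([0.3 * rng.standard_normal(t), 3.0 * rng.standard_normal(t)])
            eps.append(Epoch(data=b, label=NON_MRCP, fs=100.0, channel_names=["ch0", "ch1"]))
        return eps

    def test_filter_beats_exhaustive_angle_search(self):
        eps = self._two_class_toy()
        w = _fit_csp(eps)[0]
        c1 = np.mean([e.data @ e.data.T / e.data.shape[1]
                      for e in eps if e.label == MRCP], axis=0)
        c2 = np.mean([e.data @ e.data.T / e.data.shape[1]
                      for e in eps if e.label == NON_MRCP], axis=0)
        ratio = lambda v: (v @ c1 @ v) / (v @ c2 @ v)
        best_grid = max(
            ratio(np.array([np.cos(a), np.sin(a)]))
            for a in np.deg2rad(np.arange(360))
        )
        assert ratio(w) >= best_grid - 1e-8

    def test_filters_diagonalize_both_class_covariances(self):
        from scipy import linalg

        eps = self._two_class_toy(seed=1)
        c1 = np.mean([e.data @ e.data.T / e.data.shape[1]
                      for e in eps if e.label == MRCP], axis=0)
        c2 = np.mean([e.data @ e.data.T / e.data.shape[1]
                      for e in eps if e.label == NON_MRCP], axis=0)
        _, vecs = linalg.eigh(c1, c1 + c2)
        for c in (c1, c2):
            d = vecs.T @ c @ vecs
            off = d - np.diag(np.diag(d))
            assert np.abs(off).max() < 1e-8

    def test_single_class_rejected(self):
        eps = [e for e in self._two_class_toy() if e.label == MRCP]
        with pytest.raises(ValueError, match="both classes"):
            _fit_csp(eps)


class TestPcaIca:
    def test_pca_recovers_dominant_axis(self):
        rng = np.random.default_rng(2)
        mont = _toy_montage(3)
        axis = np.array([0.6, -0.64, 0.48])
        axis /= np.linalg.norm(axis)
        eps = []
        for i in range(6):
            src = 5.0 * rng.standard_normal(100)
            x = np.outer(axis, src) + 0.1 * rng.standard_normal((3, 100))
            eps.append(_epoch_from_matrix(x, mont.channel_names,
                                          MRCP if i % 2 else NON_MRCP))
        model = fit_spatial("PCA", eps, mont)
        cos = abs(model.weights[0] @ axis)
        assert cos > 0.99

    def test_ica_recovers_independent_sources(self):
        rng = np.random.default_rng(5)
        mont = _toy_montage(2)
        s = np.vstack([np.sign(np.sin(np.linspace(0, 40, 2000))),
                       rng.laplace(size=2000)])
        mix = np.array([[1.0, 0.6], [0.4, 1.0]])
        x = mix @ s
        eps = [
            _epoch_from_matrix(x[:, i * 500 : (i + 1) * 500], mont.channel_names,
                               MRCP if i % 2 else NON_MRCP)
            for i in range(4)
        ]
        model = fit_spatial("ICA", eps, mont, seed=0)
        assert model.fit_metadata["converged"]
        rec = model.weights @ (x - x.mean(axis=1, keepdims=True))
        corr = np.corrcoef(np.vstack([rec, s]))[:2, 2:]
        # each source matches exactly one component up to sign/permutation
        assert sorted(np.abs(corr).max(axis=1).round(3)) == sorted(
            np.abs(corr).max(axis=0).round(3)
        )
        assert np.abs(corr).max(axis=1).min() > 0.95

    def test_sign_convention_largest_element_positive(self, train_19ch, montage):
        for method in ("PCA", "ICA", "CSP"):
            model = fit_spatial(method, train_19ch, montage, seed=1)
            for row in model.weights:
                assert row[np.argmax(np.abs(row))] > 0


class TestOutputsAndShape:
    def test_nof_is_identity(self, train_19ch, montage):
        model = fit_spatial("NoF", train_19ch, montage)
        outs = apply_spatial(model, train_19ch[0])
        assert len(outs) == 19
        for i, out in enumerate(outs):
            assert np.array_equal(out.data[0], train_19ch[0].data[i])

    def test_output_cardinalities_give_2010_grid(self, train_19ch, montage):
        counts = {}
        for method in SPATIAL_METHODS:
            model = fit_spatial(method, train_19ch, montage, seed=0)
            counts[method] = model.n_outputs
            assert model.n_outputs == n_outputs(method)
        assert counts == {"NoF": 19, "SL": 9, "ICA": 19, "CSP": 1, "PCA": 19}
        assert 5 * sum(counts.values()) * 6 == 2010

    def test_channel_mismatch_rejected(self, train_19ch, montage):
        model = fit_spatial("NoF", train_19ch, montage)
        bad = Epoch(data=np.zeros((2, 10)), label=MRCP, fs=32.0,
                    channel_names=["a", "b"])
        with pytest.raises(ValueError, match="channel order"):
            apply_spatial(model, bad)


def test_spatial_model_json_round_trip(tmp_path, train_19ch, montage):
    for method in ("SL", "PCA"):
        model = fit_spatial(method, train_19ch, montage, seed=2)
        path = tmp_path / f"{method}.json"
        model.to_json(path)
        from mrcpbench.spatial import SpatialModel

        back = SpatialModel.from_json(path)
        assert back.method == model.method
        assert np.allclose(back.weights, model.weights)
        outs_a = apply_spatial(model, train_19ch[0])
        outs_b = apply_spatial(back, train_19ch[0])
        for a, b in zip(outs_a, outs_b):
            assert np.allclose(a.data, b.data)
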