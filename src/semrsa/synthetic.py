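"""Synthetic inputs with known ground truth.

Generates every input the pipeline needs: block-structured binary feature
norms (category structure induces a category-structured semantic RDM),
deterministic random word embeddings, electrode tables, and ECoG-like
cohorts in which the pairwise cosine geometry of item patterns inside a
chosen time window matches a target RDM at a chosen SNR.  Optionally the
representational signal is carried by band-limited oscillatory phase
offsets instead of broadband amplitude, and 60 Hz line noise and
saccade-shaped artifact components can be injected.

All generators are bit-reproducible given their seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phase import BandSpec
from .preprocess import ElectrodeTable, SaccadeTemplate, TrialData
from .semantic import RDM, EmbeddingTable, FeatureNorms, concept_vectors, semantic_rdm

ROIS = ("MTG", "ITG", "TP", "Fus", "PRC")


class SyntheticDataError(ValueError):
    pass


def generate_feature_norms(n_concepts: int = 20, n_features: int = 60,
                           n_categories: int = 4, p_within: float = 0.8,
                           p_between: float = 0.1, seed: int = 0) -> FeatureNorms:
    """Block-structured binary norms.

    Features are split into category blocks; a concept holds a block feature
    with probability ``p_within`` inside its own category and ``p_between``
    outside, so within-category concepts share more features than
    between-category pairs.  Every concept is guaranteed >= 1 feature.
    """
    if n_categories > n_concepts:
        raise SyntheticDataError("more categories than concepts")
    if not (0 <= p_between < p_within <= 1):
        raise SyntheticDataError("need 0 <= p_between < p_within <= 1")
    rng = np.random.default_rng(seed)
    concepts = [f"concept{i:03d}" for i in range(n_concepts)]
    features = [f"word{j:03d} trait{j:03d}" for j in range(n_features)]
    cat_of_concept = np.arange(n_concepts) % n_categories
    cat_of_feature = np.arange(n_features) % n_categories
    same = cat_of_concept[:, None] == cat_of_feature[None, :]
    prob = np.where(same, p_within, p_between)
    weights = (rng.random((n_concepts, n_features)) < prob).astype(float)
    for i in np.flatnonzero(weights.sum(axis=1) == 0):  # rejection-resample
        own = np.flatnonzero(same[i])
        weights[i, rng.choice(own)] = 1.0
    return FeatureNorms(concepts, features, weights)


def _word_rng(word: str, seed: int) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(word.encode())])


def generate_embeddings(vocab, d: int = 300, seed: int = 0) -> EmbeddingTable:
    """Unit-norm random vectors, deterministic per (word, seed)."""
    vocab = sorted(set(vocab))
    if not vocab:
        raise SyntheticDataError("empty vocabulary")
    vectors = {}
    for w in vocab:
        v = _word_rng(w, seed).standard_normal(d)
        vectors[w] = v / np.linalg.norm(v)
    return EmbeddingTable(vectors, d)


def make_model_rdm_from_norms(norms: FeatureNorms, emb: EmbeddingTable) -> RDM:
    """Composition convenience: concept vectors then cosine semantic RDM."""
    return semantic_rdm(concept_vectors(norms, emb))


def geometry_coordinates(target: RDM, tol: float = 1e-8) -> np.ndarray:
    """Unit-row coordinates whose pairwise cosine distances equal the target.

    Factors the cosine similarity Gram S = 1 - D by eigendecomposition;
    rows of the factor have unit norm (diag S = 1) and pairwise cosine
    similarity exactly S.  Raises if S is not positive semidefinite, i.e.
    the target is not realizable as a cosine geometry.
    """
    S = 1.0 - target.values
    vals, vecs = np.linalg.eigh(S)
    if vals.min() < -tol * max(1.0, vals.max()):
        raise SyntheticDataError(
            "target RDM is not a realizable cosine geometry (similarity Gram "
            "has negative eigenvalues); embed the items in a higher dimension")
    keep = vals > tol * max(1.0, vals.max())
    return vecs[:, keep] * np.sqrt(vals[keep])


def _one_over_f_noise(rng: np.random.Generator, shape: tuple, fs: float) -> np.ndarray:
    """Unit-variance noise with ~1/f power spectrum (random-phase sinusoids).

    Synthesized on a fast FFT length and cropped, for speed at awkward n.
    """
    from scipy.fft import irfft, next_fast_len

    n_t = shape[-1]
    n_fft = next_fast_len(n_t)
    freqs = np.fft.rfftfreq(n_fft, 1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** -0.5
    spec = amp * np.exp(2j * np.pi * rng.random(shape[:-1] + (len(freqs),)))
    x = irfft(spec, n=n_fft, axis=-1)[..., :n_t]
    return x / x.std()


@dataclass
class CohortSpec:
    """Study conditions for a synthetic cohort.

    Scale defaults mirror a small intracranial cohort: 8 participants,
    12 items shown 5 times each in 1 session, 2 electrodes per ROI,
    400 Hz sampling, epochs -1.5..3 s, representational effect at
    200-400 ms in the PRC.
    """

    effect_rdm: RDM
    n_participants: int = 8
    n_items: int = 12
    electrodes_per_roi: int = 2
    n_other_electrodes: int = 0    # non-ROI grid contacts (diluting the CAR)
    n_sessions: int = 1
    n_repetitions: int = 5
    fs: float = 400.0
    epoch_ms: tuple = (-1500.0, 3000.0)
    effect_window_ms: tuple = (200.0, 400.0)
    snr: float = 10.0
    gain_log_sigma: float = 0.5    # per-electrode log-normal amplifier gain
    target_roi: str = "PRC"
    phase_band: BandSpec | None = None
    line_noise_amp: float = 0.0
    artifact_rate: float = 0.0       # saccades per second
    artifact_amp: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_items != len(self.effect_rdm.items):
            self.effect_rdm = self.effect_rdm.reorder(self.effect_rdm.items[: self.n_items]) \
                if self.n_items < len(self.effect_rdm.items) else self.effect_rdm
            self.n_items = len(self.effect_rdm.items)
        if min(self.n_participants, self.n_items, self.electrodes_per_roi,
               self.n_sessions, self.n_repetitions) < 1:
            raise SyntheticDataError("all counts must be >= 1")
        lo, hi = self.effect_window_ms
        if lo < self.epoch_ms[0] or hi > self.epoch_ms[1]:
            raise SyntheticDataError("effect window outside epoch")
        if not np.isfinite(self.snr) or self.snr < 0:
            raise SyntheticDataError("snr must be finite and >= 0")


def _electrode_table(rng: np.random.Generator, per_roi: int,
                     n_other: int = 0) -> ElectrodeTable:
    rows = []
    k = 0
    for roi in ROIS + ("other",) * (n_other > 0):
        n_here = per_roi if roi != "other" else n_other
        for _ in range(n_here):
            x, y, z = rng.normal([45, 0, -30], 8)
            rows.append({"id": f"e{k:02d}", "x": round(float(x), 1),
                         "y": round(float(y), 1), "z": round(float(z), 1),
                         "roi": roi, "good": True})
            k += 1
    return ElectrodeTable(pd.DataFrame(rows))


def generate_cohort(spec: CohortSpec) -> list[dict]:
    """Per-participant (TrialData, ElectrodeTable, ground-truth record).

    Inside the effect window, each item's spatiotemporal pattern on the
    target-ROI electrodes is an orthonormal linear mixture of latent item
    coordinates realizing ``effect_rdm``'s cosine geometry, scaled to
    ``snr`` times the background-noise RMS; outside the window (and in all
    other ROIs) there is 1/f noise only.  With ``phase_band`` set, the
    geometry is instead carried by per-item phase offsets of a band-limited
    oscillation on those electrodes.
    """
    coords = geometry_coordinates(spec.effect_rdm)        # (n_items, k)
    n_items, k_dim = coords.shape
    items = list(spec.effect_rdm.items)
    times = np.arange(round(spec.epoch_ms[0] / 1000 * spec.fs),
                      round(spec.epoch_ms[1] / 1000 * spec.fs) + 1) / spec.fs * 1000.0
    n_t = len(times)
    wsel = (times >= spec.effect_window_ms[0]) & (times <= spec.effect_window_ms[1])
    n_win = int(wsel.sum())
    template = SaccadeTemplate.biphasic(spec.fs)

    child_seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_participants)
    cohort = []
    for p, ss in enumerate(child_seeds):
        rng = np.random.default_rng(ss)
        table = _electrode_table(rng, spec.electrodes_per_roi,
                                 spec.n_other_electrodes)
        n_el = len(table.frame)
        eff_idx = np.array([i for i, roi in enumerate(table.frame["roi"])
                            if roi == spec.target_roi])
        n_trials = spec.n_sessions * spec.n_repetitions * n_items
        trial_items = np.tile(np.repeat(items, spec.n_repetitions), spec.n_sessions)
        sessions = np.repeat(np.arange(spec.n_sessions),
                             spec.n_repetitions * n_items)
        # shuffle presentation order within each session
        order = np.concatenate([
            rng.permutation(spec.n_repetitions * n_items)
            + s * spec.n_repetitions * n_items
            for s in range(spec.n_sessions)])
        trial_items = trial_items[order]

        values = _one_over_f_noise(rng, (n_trials, n_el, n_t), spec.fs)
        truth: dict = {"participant": f"P{p:02d}", "window_ms": spec.effect_window_ms,
                       "target_roi": spec.target_roi, "snr": spec.snr,
                       "items": items, "seed_sequence": ss.entropy}

        if spec.snr > 0 and len(eff_idx):
            if spec.phase_band is None:
                # amplitude code: orthonormal mixture of the latent coordinates
                # expressed in a smooth temporal sine basis (vanishes at the
                # window edges, band-limited like real evoked patterns), so the
                # pattern geometry equals the target exactly and no broadband
                # transient leaks through the filters
                n_modes = min(n_win - 1, max(k_dim,
                              int(2 * 40.0 * n_win / spec.fs)))  # keep <= ~40 Hz
                p_dim = len(eff_idx) * n_modes
                if p_dim < k_dim:
                    raise SyntheticDataError(
                        f"effect pattern dim {p_dim} < latent dim {k_dim}; "
                        "use more electrodes or a longer window")
                q = np.arange(1, n_modes + 1)
                s = np.arange(n_win)
                basis = np.sin(np.pi * q[:, None] * (s[None, :] + 1) / (n_win + 1))
                basis /= np.linalg.norm(basis, axis=1, keepdims=True)
                mix, _ = np.linalg.qr(rng.standard_normal((p_dim, k_dim)))
                coef = (coords @ mix.T).reshape(n_items, len(eff_idx), n_modes)
                sig = coef @ basis                       # (items, elec, n_win)
                scale = spec.snr / sig.std()
                for tr in range(n_trials):
                    it = items.index(trial_items[tr])
                    values[np.ix_([tr], eff_idx, np.flatnonzero(wsel))] += \
                        (scale * sig[it])[None]
                truth["code"] = "amplitude"
            else:
                # phase code: item-specific phase offsets of a band oscillation
                band = spec.phase_band
                f0 = float(np.sqrt(band.lo * band.hi))
                pad_ms = 2.5 / band.lo * 1000.0          # half of a 5-cycle wavelet
                osel = ((times >= spec.effect_window_ms[0] - pad_ms)
                        & (times <= spec.effect_window_ms[1] + pad_ms))
                proj_dirs = rng.standard_normal((len(eff_idx), k_dim))
                proj_dirs /= np.linalg.norm(proj_dirs, axis=1, keepdims=True)
                phase_off = (coords @ proj_dirs.T) * (np.pi / 2)   # (items, elec)
                carrier_t = times[osel] / 1000.0
                # smooth Hann ramps over the padding keep the oscillation
                # band-limited (no item-specific broadband onset transient)
                n_sel = int(osel.sum())
                n_pad = int(round(pad_ms / 1000.0 * spec.fs))
                env = np.ones(n_sel)
                ramp = np.hanning(2 * n_pad)[:n_pad]
                env[:n_pad] = ramp
                env[-n_pad:] = ramp[::-1]
                for tr in range(n_trials):
                    it = items.index(trial_items[tr])
                    osc = spec.snr * env[None, :] * np.cos(
                        2 * np.pi * f0 * carrier_t[None, :]
                        + phase_off[it][:, None])
                    values[np.ix_([tr], eff_idx, np.flatnonzero(osel))] += osc[None]
                truth.update({"code": "phase", "band": (band.lo, band.hi),
                              "carrier_hz": f0})

        if spec.line_noise_amp > 0:
            phases = rng.uniform(0, 2 * np.pi, size=(n_trials, n_el))
            values += spec.line_noise_amp * np.cos(
                2 * np.pi * 60.0 * times[None, None, :] / 1000.0
                + phases[:, :, None])
            truth["line_noise_amp"] = spec.line_noise_amp

        if spec.artifact_rate > 0:
            maps = rng.standard_normal((2, n_el))
            maps /= np.linalg.norm(maps, axis=1, keepdims=True)
            art_idx = []
            for m in maps:
                course = np.zeros((n_trials, n_t))
                n_events = rng.poisson(spec.artifact_rate * n_t / spec.fs,
                                       size=n_trials)
                for tr in range(n_trials):
                    onsets = rng.integers(0, n_t, size=n_events[tr])
                    course[tr, onsets] = spec.artifact_amp
                course = np.apply_along_axis(
                    lambda c: np.convolve(c, template.waveform, mode="same"),
                    -1, course)
                values += course[:, None, :] * m[None, :, None]
                art_idx.append(m)
            truth.update({"artifact_maps": np.array(art_idx),
                          "artifact_rate": spec.artifact_rate})

        # per-electrode amplifier gain: channels differ in overall scale,
        # as real contacts do; applied to signal and noise alike
        gains = np.exp(rng.normal(0.0, spec.gain_log_sigma, size=n_el))
        values *= gains[None, :, None]
        truth["gains"] = gains

        trials = TrialData(trial_items, sessions[order], list(table.frame["id"]),
                           times, spec.fs, values)
        cohort.append({"trials": trials, "electrodes": table, "truth": truth})
    return cohort
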