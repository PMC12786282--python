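"""Conventional biosensing readouts and full-spectrum vectorization.

The conventional pathway splits each reflectance spectrum into four wavelength
windows (one per optical mode P1..P4), locates the resonance trough in each,
and reduces a pre/post spectrum pair to one of three readouts:

* RE (refractometric effect)  — per-mode resonance wavelength shift;
* SE (spectroscopic effect)   — per-mode change in minimum reflectance;
* NLE (nanoplasmonic loading) — both channels concatenated.

The deep-learning pathway instead keeps the whole pre/post pair, normalizes it
per wavelength with training-set statistics, and tiles it into contiguous
patches (the token sequence fed to the attention/KAN classifier).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .plasmonics import Spectrum

logger = logging.getLogger(__name__)

EFFECTS = ("RE", "SE", "NLE")

#: default half-open windows around the four configured modes, in nm
DEFAULT_WINDOWS: dict[str, tuple[float, float]] = {
    "P1": (560.0, 610.0),
    "P2": (650.0, 672.0),
    "P3": (672.0, 700.0),
    "P4": (700.0, 760.0),
}


class TroughNotFoundError(ValueError):
    """A required mode window contained no interior reflectance minimum."""


@dataclass(frozen=True)
class ModeWindows:
    """Per-mode half-open wavelength intervals ``[lo, hi)``; must not overlap."""

    windows: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_WINDOWS)
    )

    def __post_init__(self) -> None:
        items = sorted(self.windows.items(), key=lambda kv: kv[1][0])
        for label, (lo, hi) in items:
            if lo >= hi:
                raise ValueError(f"window {label} is empty: [{lo}, {hi})")
        for (la, (_, hi_a)), (lb, (lo_b, _)) in zip(items, items[1:]):
            if hi_a > lo_b:
                raise ValueError(f"windows {la} and {lb} overlap")

    @property
    def labels(self) -> list[str]:
        return list(self.windows)

    def subset(self, labels: Sequence[str]) -> "ModeWindows":
        return ModeWindows({lab: self.windows[lab] for lab in labels})


@dataclass(frozen=True)
class TroughEstimate:
    label: str
    wavelength_nm: float
    r_min: float
    found: bool = True


@dataclass(frozen=True)
class FeatureVector:
    """Ordered readout values for one pre/post pair."""

    effect: str
    mode_labels: tuple[str, ...]
    values: np.ndarray
    record_id: str = ""

    def __post_init__(self) -> None:
        if self.effect not in EFFECTS:
            raise ValueError(f"unknown effect {self.effect!r}")
        expected = len(self.mode_labels) * (2 if self.effect == "NLE" else 1)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (expected,):
            raise ValueError(f"{self.effect} vector must have length {expected}, got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("feature values must be finite")


@dataclass(frozen=True)
class PatchSequence:
    """Contiguous patches tiling a normalized pre/post spectrum pair.

    ``patches`` has shape ``(n_patches, 2 * patch_length)`` (pre channel then
    post channel per patch); ``positions`` is the contiguous 0-based patch
    index used for positional encoding; ``n_grid`` is the unpadded grid length.
    """

    patches: np.ndarray
    positions: np.ndarray
    patch_length: int
    n_grid: int

    def reconstruct(self) -> tuple[np.ndarray, np.ndarray]:
        """Undo the tiling: return the normalized (pre, post) channels, padding trimmed."""
        pre = self.patches[:, : self.patch_length].ravel()[: self.n_grid]
        post = self.patches[:, self.patch_length :].ravel()[: self.n_grid]
        return pre, post


# ---------------------------------------------------------------------------
# trough detection
# ---------------------------------------------------------------------------


def _parabolic_refine(wl: np.ndarray, r: np.ndarray, i: int) -> tuple[float, float]:
    """Sub-grid minimum from a 3-point parabola around index ``i`` (uniform grid)."""
    y0, y1, y2 = r[i - 1], r[i], r[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom <= 0:  # not locally convex; keep the grid point
        return float(wl[i]), float(y1)
    offset = 0.5 * (y0 - y2) / denom  # in grid-step units, in (-1, 1)
    step = wl[i + 1] - wl[i]
    lam = float(wl[i] + offset * step)
    r_min = float(y1 - 0.25 * (y0 - y2) * offset)
    return lam, r_min


def detect_mode_troughs(spectrum: Spectrum, windows: ModeWindows) -> list[TroughEstimate]:
    """Locate the reflectance minimum in every mode window.

    The global within-window minimum is refined by 3-point parabolic
    interpolation; ties break toward the lower wavelength.  A window whose
    minimum sits on the window edge (monotone reflectance, no interior trough)
    is flagged ``found=False`` rather than raising.
    """
    wl = spectrum.wavelength_nm
    r = spectrum.reflectance
    out = []
    for label, (lo, hi) in windows.windows.items():
        idx = np.nonzero((wl >= lo) & (wl < hi))[0]
        if idx.size < 3:
            raise ValueError(f"window {label} [{lo}, {hi}) covers fewer than 3 grid points")
        seg = r[idx]
        k = int(np.argmin(seg))  # first minimum -> lower-wavelength tie break
        if k == 0 or k == idx.size - 1:
            out.append(TroughEstimate(label, float(wl[idx[k]]), float(seg[k]), found=False))
            continue
        i = idx[k]
        lam, r_min = _parabolic_refine(wl, r, i)
        out.append(TroughEstimate(label, lam, r_min, found=True))
    return out


# ---------------------------------------------------------------------------
# RE / SE / NLE readouts
# ---------------------------------------------------------------------------


def extract_effect_features(
    pre: Spectrum,
    post: Spectrum,
    effect: str,
    windows: ModeWindows | None = None,
    record_id: str = "",
) -> FeatureVector:
    """Reduce a pre/post pair to an RE, SE or NLE readout vector.

    RE: per-mode resonance shift (post - pre, nm).  SE: per-mode change in
    minimum reflectance.  NLE: RE channels then SE channels.  Any window
    without a trough in either spectrum is a hard error for this record.
    """
    if windows is None:
        windows = ModeWindows()
    if effect not in EFFECTS:
        raise ValueError(f"unknown effect {effect!r}; expected one of {EFFECTS}")
    if not np.array_equal(pre.wavelength_nm, post.wavelength_nm):
        raise ValueError("pre and post spectra must share one wavelength grid")
    t_pre = {t.label: t for t in detect_mode_troughs(pre, windows)}
    t_post = {t.label: t for t in detect_mode_troughs(post, windows)}
    missing = [lab for lab in windows.labels if not (t_pre[lab].found and t_post[lab].found)]
    if missing:
        raise TroughNotFoundError(f"no trough in window(s) {missing} (record {record_id or '?'})")
    labels = tuple(windows.labels)
    dlam = np.array([t_post[lab].wavelength_nm - t_pre[lab].wavelength_nm for lab in labels])
    dr = np.array([t_post[lab].r_min - t_pre[lab].r_min for lab in labels])
    if effect == "RE":
        values = dlam
    elif effect == "SE":
        values = dr
    else:
        values = np.concatenate([dlam, dr])
    return FeatureVector(effect, labels, values, record_id)


# ---------------------------------------------------------------------------
# full-spectrum vectorization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NormalizationStats:
    """Per-channel (pre, post) scalar mean/s.d., frozen from the training set.

    Scalar statistics preserve the spectral lineshape: the informative
    variation stays concentrated at the resonances instead of being equalized
    across featureless baseline regions, which per-wavelength scaling would do.
    """

    mean: np.ndarray  # shape (2, 1): one scalar per channel
    std: np.ndarray  # shape (2, 1), floored away from zero

    @classmethod
    def fit(cls, pairs: Iterable[tuple[Spectrum, Spectrum]]) -> "NormalizationStats":
        pre_stack, post_stack = [], []
        for pre, post in pairs:
            pre_stack.append(pre.reflectance)
            post_stack.append(post.reflectance)
        if not pre_stack:
            raise ValueError("need at least one spectrum pair to fit normalization")
        arr = np.stack([np.stack(pre_stack), np.stack(post_stack)])  # (2, N, n_grid)
        mean = arr.mean(axis=(1, 2), keepdims=True)[:, 0]
        std = np.maximum(arr.std(axis=(1, 2), keepdims=True)[:, 0], 1e-6)
        return cls(mean, std)


def full_spectrum_vector(
    pre: Spectrum,
    post: Spectrum,
    patch_length: int = 16,
    stats: NormalizationStats | None = None,
) -> PatchSequence:
    """Normalize a pre/post pair and tile it into contiguous patches.

    The last patch is padded by edge replication when the grid length is not a
    multiple of ``patch_length``.  Without ``stats`` the raw reflectance is
    tiled unscaled.
    """
    if patch_length < 1:
        raise ValueError("patch_length must be >= 1")
    if not np.array_equal(pre.wavelength_nm, post.wavelength_nm):
        raise ValueError("pre and post spectra must share one wavelength grid")
    n = pre.wavelength_nm.size
    chans = np.stack([pre.reflectance, post.reflectance])  # (2, n)
    if stats is not None:
        if stats.mean.shape != (2, 1) or stats.std.shape != (2, 1):
            raise ValueError("normalization statistics must be one scalar per channel")
        chans = (chans - stats.mean) / stats.std
    n_patches = -(-n // patch_length)  # ceiling division
    pad = n_patches * patch_length - n
    if pad:
        chans = np.pad(chans, ((0, 0), (0, pad)), mode="edge")
    tiles = chans.reshape(2, n_patches, patch_length)
    patches = np.concatenate([tiles[0], tiles[1]], axis=1)  # (n_patches, 2*patch_length)
    return PatchSequence(patches, np.arange(n_patches), patch_length, n)


def patch_wavelength_ranges(
    wavelength_nm: np.ndarray, patch_length: int
) -> list[tuple[float, float]]:
    """Wavelength span covered by each patch (used to annotate attention maps)."""
    n = wavelength_nm.size
    n_patches = -(-n // patch_length)
    out = []
    for p in range(n_patches):
        lo = wavelength_nm[p * patch_length]
        hi = wavelength_nm[min((p + 1) * patch_length - 1, n - 1)]
        out.append((float(lo), float(hi)))
    return out


# ---------------------------------------------------------------------------
# dataset-level helpers
# ---------------------------------------------------------------------------


def feature_table(records, effect: str, windows: ModeWindows | None = None) -> pd.DataFrame:
    """Readout table for a record collection: ``record_id, effect, mode_set, f1..fK, label``.

    Records whose troughs cannot be located (possible at high noise in narrow
    windows) fail quality control and are skipped with a logged warning.
    """
    if windows is None:
        windows = ModeWindows()
    rows = []
    mode_set = "+".join(windows.labels)
    n_skipped = 0
    for rec in records:
        try:
            fv = extract_effect_features(
                rec.pre_spectrum, rec.post_spectrum, effect, windows, rec.record_id
            )
        except TroughNotFoundError:
            n_skipped += 1
            continue
        row = {"record_id": rec.record_id, "effect": effect, "mode_set": mode_set}
        row.update({f"f{i + 1}": v for i, v in enumerate(fv.values)})
        row["label"] = rec.label
        rows.append(row)
    if n_skipped:
        logger.warning("%d/%d records failed trough QC and were skipped", n_skipped, len(records))
    return pd.DataFrame(rows)


def feature_matrix(
    records, effect: str, windows: ModeWindows | None = None
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Feature matrix ``X``, labels ``y`` and subject ids for a record collection.

    Applies the same trough quality control as :func:`feature_table`.
    """
    if windows is None:
        windows = ModeWindows()
    X, y, subjects = [], [], []
    n_skipped = 0
    for rec in records:
        try:
            fv = extract_effect_features(
                rec.pre_spectrum, rec.post_spectrum, effect, windows, rec.record_id
            )
        except TroughNotFoundError:
            n_skipped += 1
            continue
        X.append(fv.values)
        y.append(rec.label)
        subjects.append(rec.subject_id)
    if n_skipped:
        logger.warning("%d/%d records failed trough QC and were skipped", n_skipped, len(records))
    if not X:
        raise TroughNotFoundError("every record failed trough quality control")
    return np.stack(X), np.asarray(y, dtype=float), subjects


def patch_tensor(
    records, patch_length: int = 16, stats: NormalizationStats | None = None
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Patch tensor ``(N, n_patches, 2*patch_length)``, labels and subject ids."""
    X, y, subjects = [], [], []
    for rec in records:
        seq = full_spectrum_vector(rec.pre_spectrum, rec.post_spectrum, patch_length, stats)
        X.append(seq.patches)
        y.append(rec.label)
        subjects.append(rec.subject_id)
    return np.stack(X), np.asarray(y, dtype=float), subjects
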