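"""Grad-CAM for 1D spectra and quantitative per-peak contribution degrees.

Gradient-weighted class activation mapping localises the wavenumber regions
a trained CNN relies on for a given class: the gradient of the class logit
is taken with respect to the last convolutional block's post-activation
feature maps, globally averaged along the length dimension to give one
weight w_i per channel, and the ReLU of the weighted sum of feature maps is
linearly upsampled to the input resolution and min-max normalised into a
heatmap over the wavenumber axis.

The heatmap is then quantified over the prominent-peak lexicon: for each
prominent peak i, S_i is the trapezoidal area of the heatmap inside the
peak's full-width-at-half-maximum window, and its contribution degree is

    C_i = S_i / sum_j S_j

so contributions over the lexicon sum to one. Group-level tables aggregate
the heatmaps of a group's correctly classified spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import StateError
from .io import LabelError, PeakLexicon, SpectrumSet
from .model import SersCNNClassifier

__all__ = [
    "Heatmap",
    "ContributionTable",
    "gradcam",
    "group_heatmap",
    "peak_fwhm_window",
    "contributions",
    "group_contribution_table",
]


@dataclass
class Heatmap:
    """Normalised non-negative contribution per wavenumber grid point."""

    axis: np.ndarray
    values: np.ndarray
    target_class: int | str
    sample_id: str = ""
    all_zero: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.axis):
            raise ValueError("heatmap length must match axis")
        if np.any(self.values < 0):
            raise ValueError("heatmap values must be non-negative")


@dataclass
class ContributionTable:
    """Per-prominent-peak FWHM areas S_i and normalised contributions C_i."""

    rows: list[dict] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.rows)

    def contributions(self) -> np.ndarray:
        return np.asarray([r["C"] for r in self.rows])

    def positions(self) -> np.ndarray:
        return np.asarray([r["position"] for r in self.rows])

    def top(self, k: int) -> list[float]:
        order = np.argsort(-self.contributions(), kind="stable")
        return [self.rows[i]["position"] for i in order[:k]]

    def to_dict(self) -> dict:
        return {"rows": self.rows, "n": self.n}


def _normalize_heatmap(values: np.ndarray) -> tuple[np.ndarray, bool]:
    top = values.max()
    if top <= 0:
        return np.zeros_like(values), True
    lo = values.min()
    return (values - lo) / (top - lo), False


def gradcam(
    clf: SersCNNClassifier, spectrum: np.ndarray, target_class: int, axis: np.ndarray
) -> Heatmap:
    """Grad-CAM heatmap of one spectrum for one target class.

    ``spectrum`` is a preprocessed intensity vector of the model's input
    length; ``axis`` is the wavenumber grid it lives on.
    """
    if not hasattr(clf, "history_"):
        raise StateError("classifier is not trained")
    if not 0 <= int(target_class) < len(clf.classes_):
        raise LabelError(f"invalid target class {target_class!r}")
    x = np.asarray(spectrum, dtype=float)[None, :]
    A = clf.feature_maps(x)  # (1, C, L_feat)
    dA = clf.grad_wrt_features(A, int(target_class))
    w = dA.mean(axis=2)  # global average pooling of gradients -> (1, C)
    cam = np.maximum((w[:, :, None] * A).sum(axis=1), 0.0)[0]
    # upsample the coarse feature-resolution map to the input grid
    coarse = np.linspace(0.0, 1.0, len(cam))
    fine = np.linspace(0.0, 1.0, x.shape[1])
    values = np.interp(fine, coarse, cam.astype(float))
    values, flat = _normalize_heatmap(values)
    return Heatmap(np.asarray(axis, dtype=float), values, target_class, all_zero=flat)


def group_heatmap(
    clf: SersCNNClassifier,
    s: SpectrumSet,
    group: str,
    correct_only: bool = True,
) -> Heatmap:
    """Mean Grad-CAM heatmap over a group's (correctly classified) spectra."""
    sub = s.select_group(group)
    if not len(sub):
        raise LabelError(f"group {group!r} has no spectra")
    X = sub.intensity_matrix()
    y = sub.labels()
    if correct_only:
        pred = clf.predict_scores(X).argmax(axis=1)
        keep = pred == y
        if not keep.any():
            raise LabelError(f"no correctly classified spectra in group {group!r}")
        X, y = X[keep], y[keep]
    maps = [gradcam(clf, X[i], int(y[i]), s.axis).values for i in range(len(X))]
    mean = np.mean(maps, axis=0)
    values, flat = _normalize_heatmap(mean)
    return Heatmap(s.axis, values, group, all_zero=flat)


def peak_fwhm_window(
    axis: np.ndarray,
    curve: np.ndarray,
    position: float,
    search_halfwidth: float,
) -> tuple[float, float, bool]:
    """Locate a peak near ``position`` and return its FWHM window.

    The local maximum is sought within ``position +/- search_halfwidth``;
    the window is the pair of half-maximum crossings found walking outward
    from the maximum, linearly interpolated between grid points. If a
    crossing is not reached before the search window's edge the window is
    clamped there and flagged. A locally all-zero curve yields a zero-width
    window, flagged.

    Returns ``(left, right, clamped_or_zero)`` in axis units.
    """
    axis = np.asarray(axis, dtype=float)
    curve = np.asarray(curve, dtype=float)
    lo = np.searchsorted(axis, position - search_halfwidth, side="left")
    hi = np.searchsorted(axis, position + search_halfwidth, side="right")
    lo, hi = max(lo, 0), min(hi, len(axis))
    if hi <= lo:
        raise ValueError("position outside axis range")
    seg = curve[lo:hi]
    j = lo + int(np.argmax(seg))
    peak = curve[j]
    if peak <= 0:
        return float(position), float(position), True
    half = peak / 2.0
    flagged = False

    def _cross(direction: int, edge: int) -> tuple[float, bool]:
        i = j
        while i != edge and curve[i + direction] > half:
            i += direction
        if i == edge:
            return float(axis[edge]), True
        a, b = i, i + direction
        # linear interpolation of the crossing between grid points a and b
        frac = (curve[a] - half) / (curve[a] - curve[b])
        return float(axis[a] + frac * (axis[b] - axis[a])), False

    left, fl = _cross(-1, lo)
    right, fr = _cross(+1, hi - 1)
    flagged = fl or fr
    return left, right, flagged


def _min_interpeak_halfwidth(lexicon: PeakLexicon) -> float:
    gaps = np.diff(lexicon.positions)
    return float(gaps.min() / 2.0) if len(gaps) else 25.0


def contributions(
    heatmap: Heatmap,
    lexicon: PeakLexicon | None = None,
    mode: str = "heatmap_peak",
    reference: np.ndarray | None = None,
) -> ContributionTable:
    """Per-peak contribution degrees C_i = S_i / sum(S_i) over the lexicon.

    ``mode='heatmap_peak'`` (default) measures each peak's FWHM window on
    the heatmap itself around the lexicon position; ``mode='spectrum_window'``
    measures the window on a supplied reference spectrum instead and
    integrates the heatmap over it. S_i is a trapezoidal integral.
    """
    lexicon = lexicon or PeakLexicon.default()
    if mode not in ("heatmap_peak", "spectrum_window"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "spectrum_window" and reference is None:
        raise ValueError("spectrum_window mode requires a reference spectrum")
    curve_for_window = heatmap.values if mode == "heatmap_peak" else np.asarray(reference)
    halfwidth = _min_interpeak_halfwidth(lexicon)
    axis = heatmap.axis
    rows = []
    areas = []
    for pos, assignment in lexicon.entries:
        left, right, flagged = peak_fwhm_window(axis, curve_for_window, pos, halfwidth)
        if right <= left:
            area = 0.0
        else:
            grid = np.linspace(left, right, 65)
            area = float(np.trapezoid(np.interp(grid, axis, heatmap.values), grid))
        areas.append(area)
        rows.append(
            dict(position=float(pos), assignment=assignment, S=area,
                 window=(left, right), flagged=flagged)
        )
    total = float(np.sum(areas))
    if total == 0:
        raise ValueError("all peak areas are zero; contributions undefined")
    for row in rows:
        row["C"] = row.pop("S") / total
        row["S"] = row["C"] * total  # keep both, C first for readability
    return ContributionTable(rows)


def group_contribution_table(
    clf: SersCNNClassifier,
    s: SpectrumSet,
    lexicon: PeakLexicon | None = None,
    mode: str = "heatmap_peak",
    correct_only: bool = True,
    aggregate: str = "mean_heatmap",
) -> dict[str, ContributionTable]:
    """Contribution tables per group.

    ``aggregate='mean_heatmap'`` (default) applies the contribution formula
    to each group's mean heatmap; ``'per_spectrum'`` computes contributions
    per spectrum and averages the C_i instead. Serialisable as a
    (17 peaks x 4 groups) percentage matrix; each group's column sums to
    100% either way.
    """
    lexicon = lexicon or PeakLexicon.default()
    if aggregate not in ("mean_heatmap", "per_spectrum"):
        raise ValueError(f"unknown aggregate {aggregate!r}")
    out: dict[str, ContributionTable] = {}
    for group in s.class_names:
        if not any(sp.group == group for sp in s):
            raise LabelError(f"group {group!r} absent from the set")
        group_mean = s.select_group(group).intensity_matrix().mean(axis=0)
        ref = group_mean if mode == "spectrum_window" else None
        if aggregate == "mean_heatmap":
            hm = group_heatmap(clf, s, group, correct_only=correct_only)
            out[group] = contributions(hm, lexicon, mode=mode, reference=ref)
            continue
        sub = s.select_group(group)
        X, y = sub.intensity_matrix(), sub.labels()
        keep = np.arange(len(X))
        if correct_only:
            keep = np.where(clf.predict_scores(X).argmax(axis=1) == y)[0]
            if not len(keep):
                raise LabelError(
                    f"no correctly classified spectra in group {group!r}"
                )
        per_c = []
        template = None
        for i in keep:
            hm = gradcam(clf, X[i], int(y[i]), s.axis)
            try:
                t = contributions(hm, lexicon, mode=mode, reference=ref)
            except ValueError:  # all-zero heatmap: skip this spectrum
                continue
            per_c.append(t.contributions())
            template = t
        if template is None:
            raise LabelError(f"all heatmaps degenerate in group {group!r}")
        mean_c = np.mean(per_c, axis=0)
        rows = []
        for row, c in zip(template.rows, mean_c):
            r = dict(row)
            r["C"] = float(c)
            r["S"] = float("nan")  # areas are not comparable across spectra
            rows.append(r)
        out[group] = ContributionTable(rows)
    return out
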