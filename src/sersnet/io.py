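"""Domain types and file I/O for serum SERS spectral datasets.

The unit of analysis is a 1D SERS measurement: a shared wavenumber axis
(Raman shift, cm^-1) with one intensity trace per measurement, tagged with a
sample identity, an optional replicate index and an optional diagnostic group.
Four groups are recognised, in canonical order: healthy controls (``healthy``),
bladder cancer (``BC``), adrenal cancer (``AC``) and acute myeloid leukemia
(``AML``). All four-class vectors and matrices produced anywhere in the
package are indexed in this order.

Spectral tables are read and written as CSV/TSV in two layouts:

* ``wide`` — first column is the wavenumber axis, one column per spectrum
  with header ``sample_id[:replicate_id][:group]``.
* ``long`` — tidy columns ``(sample_id, replicate_id, group, wavenumber,
  intensity)``.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CLASS_ORDER: tuple[str, ...] = ("healthy", "BC", "AC", "AML")

__all__ = [
    "CLASS_ORDER",
    "Spectrum",
    "SpectrumSet",
    "PeakLexicon",
    "read_spectra",
    "write_spectra",
    "average_replicates",
    "AxisMismatchError",
    "FormatError",
    "LabelError",
]


class AxisMismatchError(ValueError):
    """Spectra in one table do not share a common wavenumber axis."""


class FormatError(ValueError):
    """Malformed spectral table (non-monotone axis, missing columns, ...)."""


class LabelError(ValueError):
    """Unknown or inconsistent group label."""


def _canonical_group(label: str | None, class_names: Sequence[str]) -> str | None:
    if label is None or label == "":
        return None
    label = str(label)
    if label not in class_names:
        raise LabelError(
            f"unknown group label {label!r}; expected one of {tuple(class_names)}"
        )
    return label


@dataclass
class Spectrum:
    """One 1D SERS measurement on a strictly increasing wavenumber axis."""

    wavenumbers: np.ndarray
    intensities: np.ndarray
    sample_id: str
    replicate_id: int | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.ndim != 1 or self.intensities.ndim != 1:
            raise FormatError("wavenumbers and intensities must be 1D")
        if len(self.wavenumbers) != len(self.intensities):
            raise FormatError(
                f"axis length {len(self.wavenumbers)} != intensity length "
                f"{len(self.intensities)}"
            )
        if not np.all(np.isfinite(self.wavenumbers)) or not np.all(
            np.isfinite(self.intensities)
        ):
            raise FormatError("non-finite values in spectrum")
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise FormatError("wavenumbers must be strictly increasing")

    def __len__(self) -> int:
        return len(self.wavenumbers)

    def replace(self, **kwargs) -> "Spectrum":
        fields = dict(
            wavenumbers=self.wavenumbers,
            intensities=self.intensities,
            sample_id=self.sample_id,
            replicate_id=self.replicate_id,
            group=self.group,
        )
        fields.update(kwargs)
        return Spectrum(**fields)


@dataclass
class SpectrumSet:
    """A collection of spectra on one shared wavenumber axis.

    This is the container every pipeline stage consumes and produces.
    ``class_names`` fixes the label order used for all four-class outputs.
    """

    spectra: list[Spectrum]
    axis: np.ndarray | None = None
    class_names: tuple[str, ...] = CLASS_ORDER

    def __post_init__(self) -> None:
        if len(set(self.class_names)) != len(self.class_names):
            raise LabelError("duplicate entries in class_names")
        if self.axis is None:
            if not self.spectra:
                raise FormatError("empty SpectrumSet requires an explicit axis")
            self.axis = self.spectra[0].wavenumbers
        self.axis = np.asarray(self.axis, dtype=float)
        for s in self.spectra:
            if len(s.wavenumbers) != len(self.axis) or not np.allclose(
                s.wavenumbers, self.axis, rtol=0, atol=1e-9
            ):
                raise AxisMismatchError(
                    f"spectrum {s.sample_id!r} is not on the shared axis"
                )
            if s.group is not None and s.group not in self.class_names:
                raise LabelError(f"unknown group label {s.group!r}")

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    def intensity_matrix(self) -> np.ndarray:
        """Stack intensities into an ``(n_spectra, n_points)`` array."""
        if not self.spectra:
            return np.empty((0, len(self.axis)))
        return np.stack([s.intensities for s in self.spectra])

    def groups(self) -> list[str | None]:
        return [s.group for s in self.spectra]

    def labels(self) -> np.ndarray:
        """Integer class labels in canonical order; requires all labelled."""
        idx = {g: i for i, g in enumerate(self.class_names)}
        out = []
        for s in self.spectra:
            if s.group is None:
                raise LabelError(f"spectrum {s.sample_id!r} has no group label")
            out.append(idx[s.group])
        return np.asarray(out, dtype=int)

    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.spectra]

    def subset(self, indices: Iterable[int]) -> "SpectrumSet":
        return SpectrumSet(
            [self.spectra[i] for i in indices], self.axis, self.class_names
        )

    def select_group(self, group: str) -> "SpectrumSet":
        if group not in self.class_names:
            raise LabelError(f"unknown group {group!r}")
        picked = [s for s in self.spectra if s.group == group]
        return SpectrumSet(picked, self.axis, self.class_names)

    def with_matrix(self, X: np.ndarray, axis: np.ndarray | None = None) -> "SpectrumSet":
        """Same metadata, new intensities (and optionally a new axis)."""
        axis = self.axis if axis is None else np.asarray(axis, dtype=float)
        if X.shape != (len(self.spectra), len(axis)):
            raise FormatError(f"matrix shape {X.shape} does not match set")
        spectra = [
            Spectrum(axis, X[i], s.sample_id, s.replicate_id, s.group)
            for i, s in enumerate(self.spectra)
        ]
        return SpectrumSet(spectra, axis, self.class_names)


@dataclass
class PeakLexicon:
    """Lookup of prominent serum SERS peak positions and assignments.

    The default lexicon is the canonical 17-peak serum list spanning
    494-1654 cm^-1 with literature biochemical assignments. It is a static
    lookup: the package never infers assignments.
    """

    entries: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        positions = [p for p, _ in self.entries]
        if np.any(np.diff(positions) <= 0):
            raise FormatError("lexicon positions must be strictly increasing")

    @property
    def positions(self) -> np.ndarray:
        return np.asarray([p for p, _ in self.entries], dtype=float)

    @property
    def assignments(self) -> list[str]:
        return [a for _, a in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def default(cls) -> "PeakLexicon":
        ref = importlib.resources.files("sersnet.data") / "table1.csv"
        with importlib.resources.as_file(ref) as path:
            df = pd.read_csv(path)
        return cls(list(zip(df["position"].astype(float), df["assignment"])))

    @classmethod
    def from_csv(cls, path: str | Path) -> "PeakLexicon":
        df = pd.read_csv(path)
        return cls(list(zip(df["position"].astype(float), df["assignment"])))


# ---------------------------------------------------------------------------
# file I/O


def _delimiter(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def _parse_wide_header(header: str) -> tuple[str, int | None, str | None]:
    parts = str(header).split(":")
    sample_id = parts[0]
    replicate_id = int(parts[1]) if len(parts) > 1 and parts[1] != "" else None
    group = parts[2] if len(parts) > 2 and parts[2] != "" else None
    return sample_id, replicate_id, group


def read_spectra(
    path: str | Path,
    layout: str = "wide",
    class_names: Sequence[str] = CLASS_ORDER,
) -> SpectrumSet:
    """Read a spectral table into a :class:`SpectrumSet`.

    Parameters
    ----------
    path
        CSV or TSV file (delimiter inferred from the extension).
    layout
        ``"wide"`` or ``"long"`` (see module docstring).
    """
    sep = _delimiter(path)
    df = pd.read_csv(path, sep=sep)
    class_names = tuple(class_names)
    if layout == "wide":
        axis = df.iloc[:, 0].to_numpy(dtype=float)
        if len(axis) and np.any(np.diff(axis) <= 0):
            raise FormatError("wavenumber column must be strictly increasing")
        spectra = []
        for col in df.columns[1:]:
            sid, rid, grp = _parse_wide_header(col)
            grp = _canonical_group(grp, class_names)
            spectra.append(
                Spectrum(axis, df[col].to_numpy(dtype=float), sid, rid, grp)
            )
        return SpectrumSet(spectra, axis, class_names)
    elif layout == "long":
        required = {"sample_id", "replicate_id", "group", "wavenumber", "intensity"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"long layout missing columns {sorted(missing)}")
        spectra = []
        axis = None
        for (sid, rid, grp), sub in df.groupby(
            ["sample_id", "replicate_id", "group"], dropna=False, sort=False
        ):
            sub = sub.sort_values("wavenumber")
            w = sub["wavenumber"].to_numpy(dtype=float)
            if axis is None:
                axis = w
            elif len(w) != len(axis) or not np.allclose(w, axis, atol=1e-9):
                raise AxisMismatchError(f"sample {sid!r} is on a different axis")
            grp = None if pd.isna(grp) else _canonical_group(grp, class_names)
            rid = None if pd.isna(rid) else int(rid)
            spectra.append(
                Spectrum(w, sub["intensity"].to_numpy(dtype=float), str(sid), rid, grp)
            )
        if axis is None:
            raise FormatError("long table contains no spectra")
        return SpectrumSet(spectra, axis, class_names)
    raise ValueError(f"unknown layout {layout!r}")


def write_spectra(s: SpectrumSet, path: str | Path, layout: str = "wide") -> None:
    """Write a :class:`SpectrumSet` so that :func:`read_spectra` round-trips."""
    sep = _delimiter(path)
    if layout == "wide":
        data: dict[str, np.ndarray] = {"wavenumber": s.axis}
        for sp in s.spectra:
            parts = [sp.sample_id]
            if sp.replicate_id is not None or sp.group is not None:
                parts.append("" if sp.replicate_id is None else str(sp.replicate_id))
            if sp.group is not None:
                parts.append(sp.group)
            data[":".join(parts)] = sp.intensities
        pd.DataFrame(data).to_csv(path, sep=sep, index=False)
    elif layout == "long":
        rows = {
            "sample_id": np.repeat([sp.sample_id for sp in s.spectra], len(s.axis)),
            "replicate_id": np.repeat(
                [sp.replicate_id for sp in s.spectra], len(s.axis)
            ),
            "group": np.repeat([sp.group for sp in s.spectra], len(s.axis)),
            "wavenumber": np.tile(s.axis, len(s.spectra)),
            "intensity": s.intensity_matrix().ravel()
            if len(s)
            else np.empty(0),
        }
        pd.DataFrame(rows).to_csv(path, sep=sep, index=False)
    else:
        raise ValueError(f"unknown layout {layout!r}")


def average_replicates(s: SpectrumSet) -> SpectrumSet:
    """Collapse replicate measurements to one spectrum per sample.

    Each sample's intensities become the pointwise arithmetic mean of its
    replicates — the standard convention of averaging five measurements taken
    at different locations of a dried serum droplet into the sample's final
    SERS spectrum. Group labels must agree across a sample's replicates.
    """
    by_sample: dict[str, list[Spectrum]] = {}
    order: list[str] = []
    for sp in s.spectra:
        if sp.sample_id not in by_sample:
            order.append(sp.sample_id)
        by_sample.setdefault(sp.sample_id, []).append(sp)
    out = []
    for sid in order:
        reps = by_sample[sid]
        groups = {r.group for r in reps}
        if len(groups) > 1:
            raise LabelError(f"sample {sid!r} has conflicting group labels {groups}")
        mean = np.mean([r.intensities for r in reps], axis=0)
        out.append(Spectrum(s.axis, mean, sid, None, reps[0].group))
    return SpectrumSet(out, s.axis, s.class_names)
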