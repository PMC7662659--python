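"""Spectral dataset container, file I/O, axis trimming, and stratified partitioning.

The central object is :class:`SpectralDataset`: an absorbance matrix
(samples x wavenumbers) with a strictly monotonic wavenumber axis in cm^-1
and two nested categorical labels per sample — a geographic origin and a
variety, where every variety belongs to exactly one origin.

The canonical interchange format is a "wide" CSV: three leading columns
``sample_id``, ``origin``, ``variety`` followed by one column per wavenumber
(the header cell is the wavenumber itself).  Single spectra can also be read
from plain-numeric JCAMP-DX files and assembled through a manifest.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpectralDataset",
    "Partition",
    "REFERENCE_DESIGN",
    "read_dataset",
    "write_dataset",
    "read_jcamp",
    "trim_range",
    "stratified_split",
]

#: The nested sampling design of the walnut study: 10 varieties in 4
#: provinces with the published per-variety sample sizes and train counts.
#: Keys are variety labels; values are (origin, n_samples, n_train).
REFERENCE_DESIGN: dict[str, tuple[str, int, int]] = {
    "YangbiDapao": ("Yunnan", 20, 13),
    "YangbiCaoguo": ("Yunnan", 19, 13),
    "Hetian185": ("Xinjiang", 19, 13),
    "Xinfeng": ("Xinjiang", 20, 13),
    "Xinxin2": ("Xinjiang", 20, 13),
    "Liao4": ("Shaanxi", 20, 13),
    "Xiangling": ("Shaanxi", 20, 13),
    "Qingxiang": ("Hebei", 16, 10),
    "Liao1": ("Hebei", 18, 12),
    "Liao8": ("Hebei", 20, 13),
}


@dataclass
class SpectralDataset:
    """Absorbance spectra with a wavenumber axis and nested class labels."""

    absorbance: np.ndarray  # (n_samples, n_variables)
    wavenumbers: np.ndarray  # (n_variables,), cm^-1, strictly monotonic
    origin: np.ndarray  # (n_samples,) str
    variety: np.ndarray  # (n_samples,) str
    sample_id: np.ndarray  # (n_samples,) str, unique

    def __post_init__(self) -> None:
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.origin = np.asarray(self.origin, dtype=object)
        self.variety = np.asarray(self.variety, dtype=object)
        self.sample_id = np.asarray(self.sample_id, dtype=object)
        self._validate()
        # store the axis ascending; reverse jointly if it came in descending
        if self.wavenumbers[0] > self.wavenumbers[-1]:
            self.wavenumbers = self.wavenumbers[::-1].copy()
            self.absorbance = self.absorbance[:, ::-1].copy()

    def _validate(self) -> None:
        if self.absorbance.ndim != 2:
            raise ValueError("absorbance must be a 2-D matrix")
        n, p = self.absorbance.shape
        if self.wavenumbers.shape != (p,):
            raise ValueError(
                f"wavenumber axis length {self.wavenumbers.shape} does not "
                f"match {p} absorbance columns"
            )
        d = np.diff(self.wavenumbers)
        if p > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("wavenumber axis must be strictly monotonic")
        for name, arr in (("origin", self.origin), ("variety", self.variety),
                          ("sample_id", self.sample_id)):
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one entry per sample")
        ids, counts = np.unique(self.sample_id.astype(str), return_counts=True)
        if np.any(counts > 1):
            raise ValueError(f"duplicate sample_id: {ids[counts > 1][0]!r}")
        # nested design: a variety may not appear under two origins
        mapping: dict[str, str] = {}
        for v, o in zip(self.variety, self.origin):
            if v in mapping and mapping[v] != o:
                raise ValueError(
                    f"nesting violated: variety {v!r} appears under origins "
                    f"{mapping[v]!r} and {o!r}"
                )
            mapping[str(v)] = str(o)

    # -- convenience -----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_variables(self) -> int:
        return self.absorbance.shape[1]

    def variety_to_origin(self) -> dict[str, str]:
        return {str(v): str(o) for v, o in zip(self.variety, self.origin)}

    def subset(self, rows: np.ndarray) -> "SpectralDataset":
        """Row subset (boolean mask or integer index array)."""
        rows = np.asarray(rows)
        return SpectralDataset(
            absorbance=self.absorbance[rows],
            wavenumbers=self.wavenumbers.copy(),
            origin=self.origin[rows],
            variety=self.variety[rows],
            sample_id=self.sample_id[rows],
        )

    def select_ids(self, ids: Iterable[str]) -> "SpectralDataset":
        wanted = set(map(str, ids))
        mask = np.array([str(s) in wanted for s in self.sample_id])
        return self.subset(mask)

    def labels(self, by: str) -> np.ndarray:
        if by == "origin":
            return self.origin
        if by == "variety":
            return self.variety
        raise ValueError(f"unknown label field {by!r}")


@dataclass
class Partition:
    """Disjoint train/test split by sample id, covering all samples."""

    train_index: list[str]
    test_index: list[str]
    seed: int

    def __post_init__(self) -> None:
        overlap = set(self.train_index) & set(self.test_index)
        if overlap:
            raise ValueError(f"train/test overlap: {sorted(overlap)[:3]}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"seed": self.seed, "train": list(self.train_index),
             "test": list(self.test_index)}, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "Partition":
        d = json.loads(Path(path).read_text())
        return cls(train_index=d["train"], test_index=d["test"], seed=d["seed"])


# ---------------------------------------------------------------------------
# wide-CSV I/O

_LABEL_COLS = ("sample_id", "origin", "variety")


def write_dataset(ds: SpectralDataset, path: str | Path) -> None:
    """Write the wide-CSV dialect; repr keeps full float precision."""
    header = ",".join(list(_LABEL_COLS)
                      + [repr(float(w)) for w in ds.wavenumbers])
    lines = [header]
    for sid, o, v, row in zip(ds.sample_id, ds.origin, ds.variety,
                              ds.absorbance):
        lines.append(",".join([str(sid), str(o), str(v)]
                              + [repr(float(x)) for x in row]))
    Path(path).write_text("\n".join(lines) + "\n")


def _read_wide_csv(path: Path) -> SpectralDataset:
    df = pd.read_csv(path, dtype={c: str for c in _LABEL_COLS},
                     float_precision="round_trip")
    missing = [c for c in _LABEL_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"wide CSV missing label columns {missing}")
    spec_cols = [c for c in df.columns if c not in _LABEL_COLS]
    try:
        wn = np.array([float(c) for c in spec_cols])
    except ValueError as e:
        raise ValueError(f"non-numeric wavenumber header: {e}") from None
    ab = np.empty((len(df), len(spec_cols)))
    for j, c in enumerate(spec_cols):
        col = pd.to_numeric(df[c], errors="coerce").to_numpy()
        bad = np.nonzero(np.isnan(col) & ~df[c].isna().to_numpy())[0]
        if bad.size:
            raise ValueError(
                f"non-numeric absorbance at row {bad[0]} column {c!r}")
        if np.any(np.isnan(col)):
            raise ValueError(f"missing absorbance in column {c!r}")
        ab[:, j] = col
    return SpectralDataset(
        absorbance=ab, wavenumbers=wn,
        origin=df["origin"].to_numpy(dtype=object),
        variety=df["variety"].to_numpy(dtype=object),
        sample_id=df["sample_id"].to_numpy(dtype=object),
    )


# ---------------------------------------------------------------------------
# minimal JCAMP-DX (plain-numeric XYDATA only)

def read_jcamp(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read one spectrum from a JCAMP-DX file with ``XYDATA=(X++(Y..Y))``.

    Only uncompressed numeric tables are supported (no ASDF/DIFDUP
    packing).  Returns ``(wavenumbers, absorbance)``.
    """
    fields: dict[str, str] = {}
    y: list[float] = []
    in_table = False
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, val = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            if key == "XYDATA":
                in_table = True
                continue
            if key == "END":
                in_table = False
                continue
            fields[key] = val.strip()
            continue
        if in_table:
            toks = line.replace(",", " ").split()
            try:
                vals = [float(t) for t in toks]
            except ValueError:
                raise ValueError(
                    f"unsupported (packed?) XYDATA line in {path}: {line!r}")
            y.extend(vals[1:])  # first token on each line is the X checkpoint
    if not y:
        raise ValueError(f"no XYDATA table found in {path}")
    try:
        firstx = float(fields["FIRSTX"])
        lastx = float(fields["LASTX"])
        npoints = int(float(fields["NPOINTS"]))
    except KeyError as e:
        raise ValueError(f"JCAMP header missing {e}") from None
    if len(y) != npoints:
        raise ValueError(f"NPOINTS={npoints} but {len(y)} Y values read")
    xf = float(fields.get("XFACTOR", "1"))
    yf = float(fields.get("YFACTOR", "1"))
    x = np.linspace(firstx, lastx, npoints) * xf
    return x, np.asarray(y) * yf


def _read_jcamp_manifest(path: Path) -> SpectralDataset:
    """Assemble a dataset from a manifest CSV (sample_id, origin, variety, file)."""
    man = pd.read_csv(path, dtype=str)
    need = ["sample_id", "origin", "variety", "file"]
    missing = [c for c in need if c not in man.columns]
    if missing:
        raise ValueError(f"manifest missing columns {missing}")
    base = path.parent
    axis = None
    rows = []
    for f in man["file"]:
        x, yv = read_jcamp(base / f)
        if axis is None:
            axis = x
        elif x.shape != axis.shape or not np.allclose(x, axis):
            raise ValueError(f"spectrum {f} has a different wavenumber axis")
        rows.append(yv)
    return SpectralDataset(
        absorbance=np.vstack(rows), wavenumbers=axis,
        origin=man["origin"].to_numpy(dtype=object),
        variety=man["variety"].to_numpy(dtype=object),
        sample_id=man["sample_id"].to_numpy(dtype=object),
    )


def read_dataset(path: str | Path, format: str = "wide_csv") -> SpectralDataset:
    """Read a validated dataset from ``wide_csv`` or a ``jcamp_dx`` manifest."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "wide_csv":
        return _read_wide_csv(path)
    if format == "jcamp_dx":
        return _read_jcamp_manifest(path)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# trimming and partitioning

def trim_range(ds: SpectralDataset, lo: float, hi: float) -> SpectralDataset:
    """Keep exactly the variables with ``lo <= wavenumber <= hi`` (closed)."""
    if not lo < hi:
        raise ValueError(f"need lo < hi, got {lo} >= {hi}")
    mask = (ds.wavenumbers >= lo) & (ds.wavenumbers <= hi)
    if not mask.any():
        raise ValueError(f"no variables in range [{lo}, {hi}]")
    return SpectralDataset(
        absorbance=ds.absorbance[:, mask],
        wavenumbers=ds.wavenumbers[mask],
        origin=ds.origin, variety=ds.variety, sample_id=ds.sample_id,
    )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def stratified_split(
    ds: SpectralDataset,
    frac_train: float = 2 / 3,
    seed: int = 0,
    train_sizes: Mapping[str, int] | None = None,
) -> Partition:
    """Per-variety stratified train/test split.

    The per-variety training count defaults to round-half-up of
    ``frac_train * n``; an explicit ``train_sizes`` mapping
    (variety -> n_train) overrides it, which is how the published walnut
    design's printed partition is reproduced (see :data:`REFERENCE_DESIGN`).
    Sample selection within a variety is a seeded uniform draw.
    """
    if not 0 < frac_train < 1:
        raise ValueError(f"frac_train must be in (0,1), got {frac_train}")
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    for v in sorted(set(map(str, ds.variety))):
        ids = [str(s) for s, vv in zip(ds.sample_id, ds.variety) if str(vv) == v]
        n = len(ids)
        if n < 2:
            raise ValueError(f"variety {v!r} has fewer than 2 samples")
        if train_sizes is not None and v in train_sizes:
            k = int(train_sizes[v])
        else:
            k = _round_half_up(frac_train * n)
        k = min(max(k, 1), n - 1)
        chosen = rng.choice(n, size=k, replace=False)
        chosen_set = set(chosen.tolist())
        for i, sid in enumerate(ids):
            (train if i in chosen_set else test).append(sid)
    return Partition(train_index=train, test_index=test, seed=seed)
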