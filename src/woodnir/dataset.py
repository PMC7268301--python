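"""Container for NIR spectral matrices with per-sample metadata.

A :class:`SpectraSet` couples a wavenumber axis (cm^-1, uniformly spaced,
typically descending 9000 -> 4000 at 10 cm^-1 steps as produced by FT-NIR
instruments), an absorbance matrix with one row per scan or sample, and a
metadata table holding the reference trait (extractives content, % dry
mass), the surface angle presented to the probe (0 or 90 degrees) and a
core identifier for replicate grouping.

On-disk format is plain CSV: a wide spectral table whose first column is
the sample id and whose remaining headers are numeric wavenumbers, plus a
metadata table keyed by ``sample_id``. Lines starting with ``#`` are
treated as comments in both files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SpectraFormatError, ValidationError

#: metadata columns recognised on disk (besides sample_id)
META_COLUMNS = ("core_id", "ec", "angle")

_SPACING_RTOL = 1e-9


@dataclass
class SpectraSet:
    """Wavenumber axis + absorbance matrix + per-sample metadata.

    Parameters
    ----------
    wavenumbers
        Strictly monotone, uniformly spaced axis in cm^-1 (descending by
        convention). Length must equal the number of absorbance columns.
    absorbance
        ``(n_samples, n_wavenumbers)`` matrix of unitless absorbance.
    sample_ids
        Unique string identifiers, one per row.
    meta
        DataFrame indexed like ``sample_ids`` with columns ``core_id``,
        ``ec`` (percent dry mass) and ``angle`` (degrees, 0 or 90).
        Missing values are NaN (numeric) or None (core_id).
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    sample_ids: list[str]
    meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.absorbance.size == 0:
            self.absorbance = self.absorbance.reshape(len(self.sample_ids), len(self.wavenumbers))
        if self.meta is None:
            self.meta = pd.DataFrame(
                {c: [np.nan] * len(self.sample_ids) for c in META_COLUMNS},
                index=pd.Index(self.sample_ids, name="sample_id"),
            )
        self._validate()

    # -- invariants ------------------------------------------------------
    def _validate(self) -> None:
        n, p = self.absorbance.shape
        if p != self.wavenumbers.size:
            raise ValidationError(
                f"absorbance has {p} columns but axis has {self.wavenumbers.size} wavenumbers"
            )
        if len(self.sample_ids) != n:
            raise ValidationError(f"{len(self.sample_ids)} sample ids for {n} spectra")
        if len(set(self.sample_ids)) != n:
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise ValidationError(f"duplicate sample ids: {dupes}")
        if self.wavenumbers.size >= 2:
            d = np.diff(self.wavenumbers)
            if np.any(d == 0) or np.any(np.sign(d) != np.sign(d[0])):
                raise ValidationError("wavenumber axis is not strictly monotone")
            if np.any(np.abs(d - d[0]) > _SPACING_RTOL * np.abs(d[0])):
                raise ValidationError("wavenumber spacing is not uniform")
        if not np.all(np.isfinite(self.absorbance)):
            bad = np.argwhere(~np.isfinite(self.absorbance))
            i, j = bad[0]
            raise ValidationError(
                f"non-finite absorbance at sample {self.sample_ids[i]!r}, "
                f"wavenumber {self.wavenumbers[j]:g} (and {len(bad) - 1} more)"
            )
        if len(self.meta) != n:
            raise ValidationError(f"metadata has {len(self.meta)} rows for {n} spectra")

    # -- convenience -----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavenumbers(self) -> int:
        return self.absorbance.shape[1]

    @property
    def spacing(self) -> float:
        """Signed axis step in cm^-1 (negative for a descending axis)."""
        if self.wavenumbers.size < 2:
            return 0.0
        return float(self.wavenumbers[1] - self.wavenumbers[0])

    def response(self, name: str) -> np.ndarray:
        """Return a numeric metadata column as a float vector."""
        if name not in self.meta.columns:
            raise ValidationError(f"metadata has no field {name!r}")
        return self.meta[name].to_numpy(dtype=float)

    def subset(self, rows: np.ndarray | list[int]) -> "SpectraSet":
        rows = np.asarray(rows, dtype=int)
        return SpectraSet(
            wavenumbers=self.wavenumbers.copy(),
            absorbance=self.absorbance[rows].copy(),
            sample_ids=[self.sample_ids[i] for i in rows],
            meta=self.meta.iloc[rows].copy(),
        )

    def with_absorbance(
        self, absorbance: np.ndarray, wavenumbers: np.ndarray | None = None
    ) -> "SpectraSet":
        """Copy of this set with a new matrix (and optionally a new axis)."""
        return SpectraSet(
            wavenumbers=self.wavenumbers.copy() if wavenumbers is None else wavenumbers,
            absorbance=absorbance,
            sample_ids=list(self.sample_ids),
            meta=self.meta.copy(),
        )


def default_axis(start: float = 9000.0, stop: float = 4000.0, step: float = -10.0) -> np.ndarray:
    """The 501-point instrument grid, 9000 to 4000 cm^-1 at 10 cm^-1."""
    n = int(round((stop - start) / step)) + 1
    return start + step * np.arange(n)


def read_spectra(spectra_path: str | Path, meta_path: str | Path | None = None) -> SpectraSet:
    """Load a wide spectral CSV plus an optional metadata CSV.

    The spectral file has the sample id in the first column and numeric
    wavenumber headers for the remaining columns; the metadata file is
    keyed by ``sample_id``. Samples present in the spectra but absent
    from the metadata get missing metadata.
    """
    spectra_path = Path(spectra_path)
    try:
        df = pd.read_csv(spectra_path, dtype={0: str}, comment="#")
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise SpectraFormatError(f"{spectra_path}: malformed CSV: {exc}") from exc
    if df.shape[1] < 1:
        raise SpectraFormatError(f"{spectra_path}: no columns found")
    wn_headers = df.columns[1:]
    wavenumbers = []
    for h in wn_headers:
        try:
            wavenumbers.append(float(h))
        except ValueError:
            raise SpectraFormatError(
                f"{spectra_path}: non-numeric wavenumber header {h!r}"
            ) from None
    sample_ids = df.iloc[:, 0].tolist()
    absorbance = df.iloc[:, 1:].to_numpy(dtype=float)
    if absorbance.size and not np.all(np.isfinite(absorbance)):
        row = int(np.argwhere(~np.isfinite(absorbance))[0, 0])
        raise SpectraFormatError(
            f"{spectra_path}: missing or non-numeric absorbance in data row {row} "
            f"(sample {sample_ids[row]!r}); ragged rows are not permitted"
        )

    if meta_path is not None:
        meta = pd.read_csv(Path(meta_path), dtype={"sample_id": str, "core_id": str}, comment="#")
        if "sample_id" not in meta.columns:
            raise SpectraFormatError(f"{meta_path}: metadata lacks a sample_id column")
        if meta["sample_id"].duplicated().any():
            dupes = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"{meta_path}: duplicate sample ids {dupes}")
        meta = meta.set_index("sample_id")
        for col in META_COLUMNS:
            if col not in meta.columns:
                meta[col] = np.nan
        meta = meta.reindex(sample_ids)[list(META_COLUMNS)]
        meta.index.name = "sample_id"
    else:
        meta = None

    return SpectraSet(
        wavenumbers=np.array(wavenumbers),
        absorbance=absorbance,
        sample_ids=sample_ids,
        meta=meta,
    )


def write_spectra(
    s: SpectraSet,
    spectra_path: str | Path,
    meta_path: str | Path | None = None,
    header_comment: str | None = None,
) -> None:
    """Write a SpectraSet as the CSV pair understood by :func:`read_spectra`.

    Absorbance is written at full double precision (`%.17g`) so that a
    write/read round trip is lossless to within 1e-12.
    """
    spectra_path = Path(spectra_path)
    df = pd.DataFrame(
        s.absorbance, columns=[f"{w:.10g}" for w in s.wavenumbers], index=s.sample_ids
    )
    df.index.name = "sample_id"
    with open(spectra_path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, float_format="%.17g")
    if meta_path is not None:
        meta = s.meta.copy()
        meta.index.name = "sample_id"
        with open(meta_path, "w", encoding="utf-8") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            meta.to_csv(fh, float_format="%.17g")


def average_replicates(s: SpectraSet, group_key: str = "core_id") -> SpectraSet:
    """Average replicate scans that share a value of ``group_key``.

    Returns one spectrum per group (mean absorbance over member rows, in
    order of first appearance). Metadata fields are retained only when
    constant within the group and set missing otherwise; the group key
    value becomes the new sample id.
    """
    if group_key not in s.meta.columns:
        raise ValidationError(f"metadata has no field {group_key!r}")
    keys = s.meta[group_key]
    if keys.isna().any():
        missing = [s.sample_ids[i] for i in np.flatnonzero(keys.isna().to_numpy())]
        raise ValidationError(f"samples with missing {group_key!r}: {missing}")

    order: list = []
    members: dict = {}
    for i, k in enumerate(keys):
        if k not in members:
            members[k] = []
            order.append(k)
        members[k].append(i)

    rows, ids, meta_rows = [], [], []
    for k in order:
        idx = members[k]
        rows.append(s.absorbance[idx].mean(axis=0))
        ids.append(str(k))
        rec = {}
        for col in s.meta.columns:
            vals = s.meta[col].iloc[idx]
            uniq = vals.dropna().unique()
            same = len(uniq) == 1 and not vals.isna().any()
            rec[col] = uniq[0] if same else np.nan
        rec[group_key] = k
        meta_rows.append(rec)

    meta = pd.DataFrame(meta_rows, index=pd.Index(ids, name="sample_id"))
    return SpectraSet(
        wavenumbers=s.wavenumbers.copy(),
        absorbance=np.vstack(rows) if rows else np.empty((0, s.n_wavenumbers)),
        sample_ids=ids,
        meta=meta,
    )
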