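"""Shared data model and file I/O.

The central container is :class:`PeakTable`: a features x samples intensity
matrix with an explicit boolean missing mask, plus per-feature metadata
(m/z, retention time, optional adduct annotation).  Sample-level metadata
(batch, class, injection order) lives in :class:`SampleMeta`; a sample whose
class is empty/NA is a pooled quality-control (QC) injection.  Compound
databases for mass-based annotation are held in :class:`CompoundDB`, sorted
by monoisotopic mass so windows can be retrieved by binary search.

Intensities are stored as float64; missing cells are tracked in the mask
(values under the mask are kept as NaN and carry no information).  By
convention exact zeros in input files are treated as missing ("not
detected"), which is how most peak pickers export dropouts; the flag
``zero_as_missing`` turns this off.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PeakTable",
    "SampleMeta",
    "CompoundDB",
    "read_peak_table",
    "write_peak_table",
    "read_sample_list",
    "load_compound_db",
    "write_table",
]

_NA_STRINGS = {"", "na", "nan", "n/a", "null", "none"}

# column-header synonyms for the generic dialect (lower-cased)
_MZ_HEADERS = {"mz", "m/z", "mzmed"}
_RT_HEADERS = {"rt", "retention time", "retention_time", "retention time (min)", "rtmed"}
_ADDUCT_HEADERS = {"adduct", "adducts", "isotopes", "annotation"}

_PROGENESIS_ID = "Compound"
_PROGENESIS_MZ = "m/z"
_PROGENESIS_RT = "Retention time (min)"
_PROGENESIS_ADDUCT = "Adducts"


@dataclasses.dataclass
class PeakTable:
    """Features x samples intensity matrix with an explicit missing mask.

    Parameters
    ----------
    feature_ids : array of str
        Unique feature keys, one per row of ``values``.
    sample_ids : array of str
        Unique, ordered sample keys, one per column of ``values``.
    values : ndarray (n_features, n_samples) of float64
        Intensities; cells flagged in ``mask`` are set to NaN.
    mask : ndarray of bool, same shape
        True where the intensity is missing.
    mz, rt, adduct : optional per-feature arrays
        m/z (Th), retention time (minutes), adduct/isotope annotation text.
    """

    feature_ids: np.ndarray
    sample_ids: np.ndarray
    values: np.ndarray
    mask: np.ndarray
    mz: np.ndarray | None = None
    rt: np.ndarray | None = None
    adduct: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.feature_ids = np.asarray(self.feature_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.values = np.array(self.values, dtype=float)
        self.mask = np.array(self.mask, dtype=bool)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"intensity matrix shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape does not match intensity matrix")
        for name, ids in (("feature", self.feature_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
                raise ValueError(f"duplicate {name} ids: {dupes}")
        self.values[self.mask] = np.nan
        for attr in ("mz", "rt", "adduct"):
            v = getattr(self, attr)
            if v is not None:
                v = np.asarray(v, dtype=float if attr in ("mz", "rt") else object)
                if len(v) != len(self.feature_ids):
                    raise ValueError(f"{attr} length does not match feature count")
                setattr(self, attr, v)

    # -- basic geometry ---------------------------------------------------
    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def observed(self) -> np.ndarray:
        """Boolean matrix, True where a cell holds a measured intensity."""
        return ~self.mask

    def copy(self) -> "PeakTable":
        return PeakTable(
            self.feature_ids.copy(),
            self.sample_ids.copy(),
            self.values.copy(),
            self.mask.copy(),
            None if self.mz is None else self.mz.copy(),
            None if self.rt is None else self.rt.copy(),
            None if self.adduct is None else self.adduct.copy(),
        )

    def with_values(self, values: np.ndarray, mask: np.ndarray | None = None) -> "PeakTable":
        """New table sharing ids/metadata with replaced intensities."""
        out = self.copy()
        out.values = np.array(values, dtype=float)
        out.mask = self.mask.copy() if mask is None else np.array(mask, dtype=bool)
        out.values[out.mask] = np.nan
        return out

    def select_features(self, index: np.ndarray) -> "PeakTable":
        index = np.asarray(index)
        return PeakTable(
            self.feature_ids[index],
            self.sample_ids.copy(),
            self.values[index],
            self.mask[index],
            None if self.mz is None else self.mz[index],
            None if self.rt is None else self.rt[index],
            None if self.adduct is None else self.adduct[index],
        )

    def select_samples(self, index: np.ndarray) -> "PeakTable":
        index = np.asarray(index)
        return PeakTable(
            self.feature_ids.copy(),
            self.sample_ids[index],
            self.values[:, index],
            self.mask[:, index],
            None if self.mz is None else self.mz.copy(),
            None if self.rt is None else self.rt.copy(),
            None if self.adduct is None else self.adduct.copy(),
        )

    def sample_index(self, sample_ids: Sequence[str]) -> np.ndarray:
        """Positions of the given sample ids in this table's column order."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"samples not in peak table: {missing}")
        return np.array([pos[s] for s in sample_ids], dtype=int)

    def feature_index(self, feature_ids: Sequence[str]) -> np.ndarray:
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in feature_ids if f not in pos]
        if missing:
            raise KeyError(f"features not in peak table: {missing}")
        return np.array([pos[f] for f in feature_ids], dtype=int)

    def to_dataframe(self) -> pd.DataFrame:
        """Wide DataFrame (metadata columns + one intensity column per sample)."""
        data: dict[str, object] = {"feature": self.feature_ids}
        if self.mz is not None:
            data["mz"] = self.mz
        if self.rt is not None:
            data["rt"] = self.rt
        if self.adduct is not None:
            data["adduct"] = self.adduct
        for j, s in enumerate(self.sample_ids):
            data[str(s)] = self.values[:, j]
        return pd.DataFrame(data)


@dataclasses.dataclass
class SampleMeta:
    """Per-sample experimental design: batch, class and injection order.

    ``is_qc`` is True exactly when ``class`` is absent — pooled QC
    injections carry no biological group label.
    """

    table: pd.DataFrame  # columns: sample, batch, class, order, is_qc

    def __post_init__(self) -> None:
        t = self.table
        required = {"sample", "batch", "class", "order", "is_qc"}
        if not required.issubset(t.columns):
            raise ValueError(f"SampleMeta table missing columns: {sorted(required - set(t.columns))}")
        if t["sample"].duplicated().any():
            dupes = t.loc[t["sample"].duplicated(), "sample"].tolist()
            raise ValueError(f"duplicate sample ids in sample list: {dupes}")
        if t["order"].duplicated().any():
            raise ValueError("injection order values must be unique")
        self.table = t.reset_index(drop=True)

    @classmethod
    def from_columns(cls, sample, batch, klass, order) -> "SampleMeta":
        klass = [None if (k is None or (isinstance(k, float) and np.isnan(k))) else str(k) for k in klass]
        t = pd.DataFrame(
            {
                "sample": [str(s) for s in sample],
                "batch": [str(b) for b in batch],
                "class": klass,
                "order": np.asarray(order, dtype=int),
                "is_qc": [k is None for k in klass],
            }
        )
        return cls(t)

    def for_samples(self, sample_ids: Sequence[str]) -> pd.DataFrame:
        """Metadata rows aligned to the given sample order; error if any absent."""
        idx = self.table.set_index("sample")
        missing = [s for s in sample_ids if s not in idx.index]
        if missing:
            raise KeyError(f"samples missing from sample list: {missing}")
        return idx.loc[list(sample_ids)].reset_index()

    def qc_mask(self, sample_ids: Sequence[str]) -> np.ndarray:
        return self.for_samples(sample_ids)["is_qc"].to_numpy(dtype=bool)

    def classes(self, sample_ids: Sequence[str]) -> np.ndarray:
        return self.for_samples(sample_ids)["class"].to_numpy(dtype=object)

    def batches(self, sample_ids: Sequence[str]) -> np.ndarray:
        return self.for_samples(sample_ids)["batch"].to_numpy(dtype=object)

    def orders(self, sample_ids: Sequence[str]) -> np.ndarray:
        return self.for_samples(sample_ids)["order"].to_numpy(dtype=int)

    def groups(self) -> list[str]:
        """Distinct non-QC class labels, in order of first appearance."""
        seen: list[str] = []
        for k in self.table["class"]:
            if k is not None and k not in seen:
                seen.append(k)
        return seen


@dataclasses.dataclass
class CompoundDB:
    """Compound records sorted ascending by monoisotopic mass (Da)."""

    records: pd.DataFrame  # columns: compound_id, name, formula, monoisotopic_mass
    n_rejected: int = 0

    def __post_init__(self) -> None:
        r = self.records
        required = {"compound_id", "name", "formula", "monoisotopic_mass"}
        if not required.issubset(r.columns):
            raise ValueError(f"compound DB missing columns: {sorted(required - set(r.columns))}")
        if r["compound_id"].duplicated().any():
            raise ValueError("duplicate compound_id in database")
        if (r["monoisotopic_mass"] <= 0).any():
            raise ValueError("monoisotopic_mass must be positive")
        self.records = r.sort_values("monoisotopic_mass", kind="mergesort").reset_index(drop=True)
        self._masses = self.records["monoisotopic_mass"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.records)

    def query_mass_window(self, lo: float, hi: float) -> pd.DataFrame:
        """All records with lo <= monoisotopic_mass <= hi (binary search)."""
        i = int(np.searchsorted(self._masses, lo, side="left"))
        j = int(np.searchsorted(self._masses, hi, side="right"))
        return self.records.iloc[i:j]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_peak_table(
    path: str | Path,
    dialect: str = "generic",
    sample_ids: Sequence[str] | None = None,
    zero_as_missing: bool = True,
) -> PeakTable:
    """Read a wide peak table (CSV/TSV).

    ``dialect="generic"``: first column is the feature id; columns whose
    header (case-insensitively) matches known m/z, retention-time or adduct
    names become feature metadata; every other column is a sample.
    ``dialect="progenesis_qi"``: Progenesis QI csv export headers
    ("Compound", "m/z", "Retention time (min)", optional "Adducts").

    If ``sample_ids`` is given, intensity columns are checked against it and
    any mismatch is a hard error naming the offending columns.  Empty cells,
    "NA" and (by default) exact zeros become missing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    if df.columns.duplicated().any():
        raise ValueError("duplicate column headers in peak table")

    if dialect == "progenesis_qi":
        if _PROGENESIS_ID not in df.columns:
            raise ValueError(f'progenesis_qi dialect requires a "{_PROGENESIS_ID}" column')
        id_col = _PROGENESIS_ID
        mz_col = _PROGENESIS_MZ if _PROGENESIS_MZ in df.columns else None
        rt_col = _PROGENESIS_RT if _PROGENESIS_RT in df.columns else None
        adduct_col = _PROGENESIS_ADDUCT if _PROGENESIS_ADDUCT in df.columns else None
    elif dialect == "generic":
        id_col = df.columns[0]
        mz_col = rt_col = adduct_col = None
        for c in df.columns[1:]:
            lc = c.strip().lower()
            if lc in _MZ_HEADERS and mz_col is None:
                mz_col = c
            elif lc in _RT_HEADERS and rt_col is None:
                rt_col = c
            elif lc in _ADDUCT_HEADERS and adduct_col is None:
                adduct_col = c
    else:
        raise ValueError(f"unknown dialect {dialect!r}; use 'generic' or 'progenesis_qi'")

    meta_cols = {id_col} | {c for c in (mz_col, rt_col, adduct_col) if c is not None}
    intensity_cols = [c for c in df.columns if c not in meta_cols]
    if sample_ids is not None:
        wanted = [str(s) for s in sample_ids]
        extra = sorted(set(intensity_cols) - set(wanted))
        absent = [s for s in wanted if s not in intensity_cols]
        if extra or absent:
            raise ValueError(
                f"sample columns do not match the sample list; "
                f"unexpected columns: {extra}; missing columns: {absent}"
            )
        intensity_cols = wanted

    feature_ids = df[id_col].astype(str).to_numpy(dtype=object)
    if pd.Index(feature_ids).duplicated().any():
        dupes = pd.Index(feature_ids)[pd.Index(feature_ids).duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature ids: {dupes}")

    raw = df[intensity_cols].to_numpy(dtype=object)
    values = np.empty(raw.shape, dtype=float)
    mask = np.zeros(raw.shape, dtype=bool)
    for (i, j), cell in np.ndenumerate(raw):
        text = str(cell).strip()
        if text.lower() in _NA_STRINGS:
            mask[i, j] = True
            values[i, j] = np.nan
            continue
        v = float(text)
        if v < 0:
            raise ValueError(f"negative intensity at feature {feature_ids[i]!r}, column {intensity_cols[j]!r}")
        if zero_as_missing and v == 0.0:
            mask[i, j] = True
            values[i, j] = np.nan
        else:
            values[i, j] = v

    def _float_col(col):
        if col is None:
            return None
        out = pd.to_numeric(df[col].replace(dict.fromkeys(["", "NA", "na"], np.nan)), errors="coerce")
        return out.to_numpy(dtype=float)

    adduct = None
    if adduct_col is not None:
        adduct = np.array(
            [None if str(a).strip().lower() in _NA_STRINGS else str(a).strip() for a in df[adduct_col]],
            dtype=object,
        )
    return PeakTable(
        feature_ids,
        np.array(intensity_cols, dtype=object),
        values,
        mask,
        _float_col(mz_col),
        _float_col(rt_col),
        adduct,
    )


def write_peak_table(pt: PeakTable, path: str | Path) -> None:
    """Write a PeakTable as CSV/TSV; missing cells become empty fields.

    Floats are written with enough digits (%.17g) that a read round-trips
    bit-exactly.
    """
    path = Path(path)
    df = pt.to_dataframe()
    float_cols = [c for c in df.columns if df[c].dtype.kind == "f"]
    out = df.copy()
    for c in float_cols:
        out[c] = [("" if not np.isfinite(v) else f"{v:.17g}") for v in df[c]]
    out.to_csv(path, sep=_sep_for(path), index=False)


def read_sample_list(path: str | Path) -> SampleMeta:
    """Read the tab-delimited sample list (columns sample/batch/class/order).

    A row whose class field is empty or "NA" is a QC injection.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["sample", "batch", "class", "order"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"sample list missing required columns: {missing}")
    try:
        order = df["order"].astype(int)
    except ValueError as exc:
        raise ValueError(f"non-integer injection order in sample list: {exc}") from None
    klass = [None if k.strip().lower() in _NA_STRINGS else k.strip() for k in df["class"]]
    return SampleMeta.from_columns(df["sample"], df["batch"], klass, order)


def load_compound_db(path: str | Path) -> CompoundDB:
    """Load a compound database TSV (id, name, formula, monoisotopic mass).

    Rows with non-positive mass are rejected with a warning; the count of
    rejected rows is kept on the returned object.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    colmap = {}
    for c in df.columns:
        lc = c.strip().lower()
        if lc in {"id", "compound_id", "accession", "hmdb"}:
            colmap[c] = "compound_id"
        elif lc == "name":
            colmap[c] = "name"
        elif lc == "formula":
            colmap[c] = "formula"
        elif lc in {"monoisotopic_mass", "mass", "monoisotopic mass", "exact_mass"}:
            colmap[c] = "monoisotopic_mass"
    df = df.rename(columns=colmap)
    required = ["compound_id", "name", "formula", "monoisotopic_mass"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"compound DB missing required columns: {missing}")
    mass = pd.to_numeric(df["monoisotopic_mass"], errors="coerce")
    bad = ~(mass > 0)
    n_rejected = int(bad.sum())
    if n_rejected:
        warnings.warn(f"rejected {n_rejected} compound rows with non-positive or unparseable mass")
    kept = df.loc[~bad, required].copy()
    kept["monoisotopic_mass"] = mass[~bad].astype(float)
    return CompoundDB(kept.reset_index(drop=True), n_rejected=n_rejected)


def write_table(table: pd.DataFrame, path: str | Path, format: str | None = None) -> None:
    """Write any tabular result as CSV or TSV with lossless float precision."""
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "tsv"
    if format not in ("csv", "tsv"):
        raise ValueError(f"unknown format {format!r}; use 'csv' or 'tsv'")
    sep = "," if format == "csv" else "\t"
    table.to_csv(path, sep=sep, index=False, float_format="%.12g")
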