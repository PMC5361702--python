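"""Putative metabolite identification by accurate-mass matching.

Each feature's m/z is converted to a neutral monoisotopic mass under one
or more adduct hypotheses (M = mz·z − mass_shift, with electron-corrected
shift masses), and compounds whose database mass lies within a ppm
tolerance are retrieved by binary search over the mass-sorted database.
The mass error convention is delta_ppm = (inferred − db)/db × 1e6, so an
observed mass heavier than the database entry gives a positive delta.
When a feature carries an adduct annotation from upstream peak grouping,
only that adduct is tried; isotope peaks (annotations naming no known
adduct) are skipped.  The default tolerance is 10 ppm.
"""

from __future__ import annotations

import dataclasses

import pandas as pd

from .core_io import CompoundDB, PeakTable

__all__ = [
    "AdductRule",
    "IdentificationHit",
    "BUILTIN_ADDUCTS",
    "infer_neutral_mass",
    "match_features",
    "hits_table",
]

_PROTON = 1.00728  # electron-corrected proton mass, Da


@dataclasses.dataclass(frozen=True)
class AdductRule:
    """Ion-forming rule: observed mz = (M + mass_shift) / charge."""

    name: str
    mass_shift: float  # Da, signed
    charge: int = 1
    polarity: str = "positive"

    def __post_init__(self):
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        if self.polarity not in ("positive", "negative"):
            raise ValueError("polarity must be 'positive' or 'negative'")


BUILTIN_ADDUCTS: dict[str, AdductRule] = {
    a.name: a
    for a in [
        AdductRule("[M+H]+", _PROTON, 1, "positive"),
        AdductRule("[M+Na]+", 22.98922, 1, "positive"),
        AdductRule("[M+K]+", 38.96316, 1, "positive"),
        AdductRule("[M+NH4]+", 18.03383, 1, "positive"),
        AdductRule("[M-H]-", -_PROTON, 1, "negative"),
    ]
}


@dataclasses.dataclass
class IdentificationHit:
    """One feature-to-compound match within tolerance."""

    feature: str
    compound_id: str
    name: str
    formula: str
    db_mass: float
    inferred_neutral_mass: float
    delta_ppm: float
    adduct: str


def infer_neutral_mass(mz: float, adduct: AdductRule) -> float:
    """Neutral monoisotopic mass M = mz·charge − mass_shift."""
    if mz <= 0:
        raise ValueError("m/z must be positive")
    m = mz * adduct.charge - adduct.mass_shift
    if m <= 0:
        raise ValueError(f"non-positive neutral mass for mz={mz} under {adduct.name}")
    return m


def match_features(
    pt: PeakTable,
    db: CompoundDB,
    tol_ppm: float = 10.0,
    adducts: list[AdductRule] | None = None,
    polarity: str | None = None,
    use_annotations: bool = True,
) -> list[IdentificationHit]:
    """Match every feature's m/z against the compound database.

    For each feature: if ``use_annotations`` and the feature carries an
    adduct annotation, only the matching rule from ``adducts`` is tried
    (features annotated with something that is no known adduct — isotope
    peaks — are skipped); otherwise every rule (optionally restricted to
    one ``polarity``) is tried.  All compounds within ``tol_ppm`` are
    returned, sorted per feature by |delta_ppm|.
    """
    if adducts is None:
        adducts = list(BUILTIN_ADDUCTS.values())
    if not adducts:
        raise ValueError("adduct list must be nonempty")
    if polarity is not None:
        adducts = [a for a in adducts if a.polarity == polarity]
        if not adducts:
            raise ValueError(f"no adduct rules with polarity {polarity!r}")
    if pt.mz is None:
        raise ValueError("peak table has no m/z values")
    by_name = {a.name: a for a in adducts}
    tol = tol_ppm * 1e-6
    hits: list[IdentificationHit] = []
    for i, fid in enumerate(pt.feature_ids):
        mz = pt.mz[i]
        if not (mz and mz > 0):
            continue
        annotation = pt.adduct[i] if (use_annotations and pt.adduct is not None) else None
        if annotation:
            rule = by_name.get(str(annotation).strip())
            if rule is None:
                continue  # isotope or unknown ion form: skip
            rules = [rule]
        else:
            rules = adducts
        feature_hits: list[IdentificationHit] = []
        for rule in rules:
            try:
                neutral = infer_neutral_mass(float(mz), rule)
            except ValueError:
                continue
            lo = neutral / (1.0 + tol)
            hi = neutral / (1.0 - tol)
            window = db.query_mass_window(lo, hi)
            for _, rec in window.iterrows():
                delta = (neutral - rec["monoisotopic_mass"]) / rec["monoisotopic_mass"] * 1e6
                if abs(delta) <= tol_ppm:
                    feature_hits.append(
                        IdentificationHit(
                            feature=str(fid),
                            compound_id=str(rec["compound_id"]),
                            name=str(rec["name"]),
                            formula=str(rec["formula"]),
                            db_mass=float(rec["monoisotopic_mass"]),
                            inferred_neutral_mass=float(neutral),
                            delta_ppm=float(delta),
                            adduct=rule.name,
                        )
                    )
        feature_hits.sort(key=lambda h: abs(h.delta_ppm))
        hits.extend(feature_hits)
    return hits


def hits_table(hits: list[IdentificationHit]) -> pd.DataFrame:
    """Identification hits as a flat DataFrame (TSV-ready)."""
    return pd.DataFrame([dataclasses.asdict(h) for h in hits])
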