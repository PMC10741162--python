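"""Accurate-mass and fragment-based metabolite annotation.

Theoretical adduct m/z values are derived from elemental formulas using
monoisotopic atomic masses and explicit proton/electron bookkeeping.
Features match a database compound at confidence level 3 when the mass
error is within the ppm tolerance (default 10 ppm); level 2 additionally
requires at least five shared MS/MS fragment masses; level 1 further
requires a retention-time match to an authentic-standard database entry.
The level scheme follows the standard high-resolution MS identification
confidence scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .datamodel import CompoundRecord, FeatureMeta, Spectrum, ValidationError

#: monoisotopic atomic masses, Da
MONOISOTOPIC_MASS = {
    "C": 12.000000,
    "H": 1.00782503,
    "N": 14.00307401,
    "O": 15.99491462,
    "S": 31.97207117,
    "P": 30.97376163,
    "Na": 22.98976928,
    "K": 38.96370649,
    "Cl": 34.96885268,
}

ELECTRON_MASS = 0.00054858
PROTON_MASS = MONOISOTOPIC_MASS["H"] - ELECTRON_MASS  # 1.00727645
WATER_MASS = 2 * MONOISOTOPIC_MASS["H"] + MONOISOTOPIC_MASS["O"]

#: adduct -> (mass shift relative to the neutral monoisotopic mass, polarity)
ADDUCTS: dict[str, tuple[float, str]] = {
    "[M+H]+": (PROTON_MASS, "pos"),
    "[M+Na]+": (MONOISOTOPIC_MASS["Na"] - ELECTRON_MASS, "pos"),
    "[M+H-H2O]+": (PROTON_MASS - WATER_MASS, "pos"),
    "[M-H]-": (-PROTON_MASS, "neg"),
    "[M+Cl]-": (MONOISOTOPIC_MASS["Cl"] + ELECTRON_MASS, "neg"),
}


@dataclass
class AnnotationHit:
    """One feature-to-compound match with its evidence level."""

    feature_id: str
    compound: str
    kegg_id: str | None
    adduct: str
    theoretical_mz: float
    ppm_error: float
    level: int = 3
    n_shared_fragments: int | None = None


def monoisotopic_mass(formula: Mapping[str, int]) -> float:
    """Neutral monoisotopic mass of an elemental formula, Da."""
    if not formula:
        raise ValidationError("empty formula")
    total = 0.0
    for el, n in formula.items():
        if el not in MONOISOTOPIC_MASS:
            raise ValidationError(f"unsupported element {el!r}")
        if n <= 0:
            raise ValidationError(f"element count for {el} must be positive")
        total += n * MONOISOTOPIC_MASS[el]
    return total


def adduct_mz(neutral_mass: float, adduct: str) -> float:
    """m/z of a (singly charged) adduct of a neutral monoisotopic mass."""
    if neutral_mass <= 0:
        raise ValidationError("neutral mass must be positive")
    if adduct not in ADDUCTS:
        raise ValidationError(f"unknown adduct label {adduct!r}")
    return neutral_mass + ADDUCTS[adduct][0]


def ppm_error(observed: float, theoretical: float) -> float:
    return abs(observed - theoretical) / theoretical * 1e6


def match_features_level3(
    features: Sequence[FeatureMeta],
    db: Sequence[CompoundRecord],
    tol_ppm: float = 10.0,
    adducts: Iterable[str] = tuple(ADDUCTS),
) -> list[AnnotationHit]:
    """Accurate-mass (level 3) matching of features against the database.

    Every polarity-compatible (compound, adduct) pair within ``tol_ppm``
    becomes a hit; hits are sorted per feature by ascending ppm error,
    ties alphabetically by compound name.
    """
    if not db:
        raise ValidationError("compound database is empty")
    neutral = [(rec, monoisotopic_mass(rec.formula)) for rec in db]
    hits: list[AnnotationHit] = []
    for feat in features:
        feat_hits = []
        for rec, mass in neutral:
            for adduct in adducts:
                shift, polarity = ADDUCTS[adduct]
                if polarity != feat.mode:
                    continue
                theo = mass + shift
                if theo <= 0:
                    continue
                err = ppm_error(feat.mz, theo)
                if err <= tol_ppm:
                    feat_hits.append(AnnotationHit(
                        feature_id=feat.feature_id,
                        compound=rec.name,
                        kegg_id=rec.kegg_id,
                        adduct=adduct,
                        theoretical_mz=theo,
                        ppm_error=err,
                    ))
        feat_hits.sort(key=lambda h: (h.ppm_error, h.compound))
        hits.extend(feat_hits)
    return hits


def shared_fragments(experimental, reference, tol_da: float = 0.01) -> int:
    """Greedy one-to-one fragment matching, closest pairs first; matched
    pairs are disjoint (no reference fragment is counted twice)."""
    exp = np.asarray(experimental, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if exp.size == 0 or ref.size == 0:
        return 0
    pairs = sorted(
        ((abs(e - r), i, j) for i, e in enumerate(exp) for j, r in enumerate(ref)),
        key=lambda t: t[0],
    )
    used_e: set[int] = set()
    used_r: set[int] = set()
    n = 0
    for diff, i, j in pairs:
        if diff > tol_da:
            break
        if i in used_e or j in used_r:
            continue
        used_e.add(i)
        used_r.add(j)
        n += 1
    return n


def msms_upgrade(
    hits: Sequence[AnnotationHit],
    spectra: Mapping[str, Spectrum | Sequence[float]],
    db: Sequence[CompoundRecord],
    features: Sequence[FeatureMeta] | None = None,
    frag_tol_da: float = 0.01,
    min_shared: int = 5,
    rt_tol_min: float = 0.2,
) -> list[AnnotationHit]:
    """Upgrade level-3 hits using MS/MS fragment evidence.

    A hit becomes level 2 when at least ``min_shared`` experimental
    fragments match database fragments within ``frag_tol_da``; it becomes
    level 1 when additionally the database record is an authentic
    standard whose retention time is within ``rt_tol_min`` minutes of the
    feature.  Hits without spectra or database fragments are unchanged.
    """
    by_name = {rec.name: rec for rec in db}
    feat_rt = {f.feature_id: f.rt for f in features} if features else {}
    out: list[AnnotationHit] = []
    for hit in hits:
        rec = by_name.get(hit.compound)
        spec = spectra.get(hit.feature_id)
        upgraded = AnnotationHit(**vars(hit))
        if rec is not None and rec.fragments and spec is not None:
            exp = spec.mz if isinstance(spec, Spectrum) else np.asarray(spec, dtype=float)
            n = shared_fragments(exp, rec.fragments, tol_da=frag_tol_da)
            upgraded.n_shared_fragments = n
            if n >= min_shared:
                upgraded.level = 2
                rt = feat_rt.get(hit.feature_id)
                if (rec.is_standard and rec.rt is not None and rt is not None
                        and abs(rt - rec.rt) <= rt_tol_min):
                    upgraded.level = 1
        out.append(upgraded)
    return out
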