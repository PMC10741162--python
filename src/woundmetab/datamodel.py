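"""Shared data model for the wound-metabolomics pipeline.

The central object is :class:`FeatureTable`: an intensity matrix of LC-MS
features (rows) by injections (columns), carrying per-feature metadata
(m/z, retention time, ionization mode) and per-sample metadata (injection
order, pooled-QC vs study biopsy, pig, wound type, treatment, day).
Every pipeline stage consumes and produces validated feature tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class WoundMetabError(Exception):
    """Base class for package errors."""


class ValidationError(WoundMetabError):
    """A data object violates one of its invariants."""


class ParseError(WoundMetabError):
    """An on-disk artifact could not be parsed."""


MODES = ("pos", "neg")
WOUND_TYPES = ("DPT", "FT")
TREATMENTS = ("AFSG", "FBD", "CS", "STSG_sandwich")
DAYS = (7, 14, 21, 28, 60)

MZ_RANGE = (50.0, 1000.0)   # instrument scan range, Da
RT_RANGE = (0.0, 10.0)      # chromatographic gradient length, min


@dataclass(frozen=True)
class FeatureMeta:
    """One detected (m/z, retention time) pair in one ionization mode."""

    feature_id: str
    mz: float
    rt: float
    mode: str

    def validate(self) -> None:
        if not self.feature_id:
            raise ValidationError("feature_id must be nonempty")
        if not (MZ_RANGE[0] <= self.mz <= MZ_RANGE[1]):
            raise ValidationError(
                f"feature {self.feature_id!r}: mz {self.mz} outside scan range {MZ_RANGE}"
            )
        if not (RT_RANGE[0] <= self.rt <= RT_RANGE[1]):
            raise ValidationError(
                f"feature {self.feature_id!r}: rt {self.rt} outside gradient {RT_RANGE}"
            )
        if self.mode not in MODES:
            raise ValidationError(
                f"feature {self.feature_id!r}: mode {self.mode!r} not in {MODES}"
            )


@dataclass(frozen=True)
class SampleMeta:
    """One injection: either a pooled QC or a study biopsy."""

    sample_id: str
    injection_order: int
    kind: str  # "QC" | "study"
    pig_id: str | None = None
    wound_type: str | None = None
    treatment: str | None = None
    day: int | None = None

    def validate(self) -> None:
        if not self.sample_id:
            raise ValidationError("sample_id must be nonempty")
        if not (isinstance(self.injection_order, (int, np.integer)) and self.injection_order >= 1):
            raise ValidationError(
                f"sample {self.sample_id!r}: injection_order must be a positive integer"
            )
        if self.kind == "QC":
            if any(v is not None for v in (self.pig_id, self.wound_type, self.treatment, self.day)):
                raise ValidationError(
                    f"QC sample {self.sample_id!r} must not carry study metadata"
                )
        elif self.kind == "study":
            if any(v is None for v in (self.pig_id, self.wound_type, self.treatment, self.day)):
                raise ValidationError(
                    f"study sample {self.sample_id!r} must carry pig/wound/treatment/day"
                )
            if self.wound_type not in WOUND_TYPES:
                raise ValidationError(
                    f"sample {self.sample_id!r}: wound_type {self.wound_type!r} not in {WOUND_TYPES}"
                )
            if self.treatment not in TREATMENTS:
                raise ValidationError(
                    f"sample {self.sample_id!r}: treatment {self.treatment!r} not in {TREATMENTS}"
                )
        else:
            raise ValidationError(f"sample {self.sample_id!r}: kind {self.kind!r} not in (QC, study)")


#: elements supported in compound formulas
KNOWN_ELEMENTS = ("C", "H", "N", "O", "P", "S", "Na", "K", "Cl")


@dataclass
class CompoundRecord:
    """A database compound: name, elemental formula, optional KEGG id,
    optional reference fragment masses, optional authentic-standard RT."""

    name: str
    formula: dict[str, int]
    kegg_id: str | None = None
    fragments: list[float] | None = None
    rt: float | None = None
    is_standard: bool = False

    def validate(self) -> None:
        if not self.name:
            raise ValidationError("compound name must be nonempty")
        if not self.formula:
            raise ValidationError(f"compound {self.name!r}: empty formula")
        for el, n in self.formula.items():
            if el not in KNOWN_ELEMENTS:
                raise ValidationError(f"compound {self.name!r}: unknown element {el!r}")
            if not (isinstance(n, (int, np.integer)) and n > 0):
                raise ValidationError(f"compound {self.name!r}: count for {el} must be > 0")
        if self.fragments is not None and any(f <= 0 for f in self.fragments):
            raise ValidationError(f"compound {self.name!r}: fragment m/z must be > 0")


@dataclass
class PathwayGraph:
    """A pathway as an undirected compound graph (KEGG compound ids)."""

    pathway_id: str
    name: str
    nodes: set[str] = field(default_factory=set)
    edges: set[frozenset[str]] = field(default_factory=set)

    def validate(self) -> None:
        for edge in self.edges:
            if len(edge) != 2:
                raise ValidationError(
                    f"pathway {self.pathway_id!r}: self-loop or malformed edge {set(edge)}"
                )
            if not edge <= self.nodes:
                raise ValidationError(
                    f"pathway {self.pathway_id!r}: edge {set(edge)} has endpoint outside nodes"
                )

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(sorted(self.nodes))
        g.add_edges_from(tuple(sorted(e)) for e in self.edges)
        return g


@dataclass
class Spectrum:
    """An MS/MS spectrum: fragment m/z values with intensities."""

    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValidationError("spectrum mz and intensity lengths differ")


@dataclass
class FeatureTable:
    """Feature x injection intensity matrix with aligned metadata.

    ``intensities[i, j]`` is the (nonnegative) abundance of feature ``i``
    in injection ``j``; missing measurements are NaN, never zero.
    """

    intensities: np.ndarray
    features: list[FeatureMeta]
    samples: list[SampleMeta]

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        if self.intensities.ndim != 2:
            raise ValidationError("intensities must be a 2-d matrix")
        n_f, n_s = self.intensities.shape
        if n_f != len(self.features):
            raise ValidationError(
                f"row count {n_f} != number of feature records {len(self.features)}"
            )
        if n_s != len(self.samples):
            raise ValidationError(
                f"column count {n_s} != number of sample records {len(self.samples)}"
            )
        for f in self.features:
            f.validate()
        for s in self.samples:
            s.validate()
        fids = [f.feature_id for f in self.features]
        if len(set(fids)) != len(fids):
            dup = sorted({x for x in fids if fids.count(x) > 1})
            raise ValidationError(f"duplicate feature ids: {dup}")
        sids = [s.sample_id for s in self.samples]
        if len(set(sids)) != len(sids):
            dup = sorted({x for x in sids if sids.count(x) > 1})
            raise ValidationError(f"duplicate sample ids: {dup}")
        orders = [s.injection_order for s in self.samples]
        if len(set(orders)) != len(orders):
            raise ValidationError("duplicate injection orders")
        with np.errstate(invalid="ignore"):
            if np.any(self.intensities < 0):
                raise ValidationError("negative intensity encountered")

    # -- accessors --------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape

    @property
    def feature_ids(self) -> list[str]:
        return [f.feature_id for f in self.features]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def qc_mask(self) -> np.ndarray:
        return np.array([s.kind == "QC" for s in self.samples], dtype=bool)

    def study_mask(self, wound_type: str | None = None) -> np.ndarray:
        return np.array(
            [
                s.kind == "study" and (wound_type is None or s.wound_type == wound_type)
                for s in self.samples
            ],
            dtype=bool,
        )

    def injection_orders(self) -> np.ndarray:
        return np.array([s.injection_order for s in self.samples], dtype=int)

    def feature_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mz": [f.mz for f in self.features],
                "rt": [f.rt for f in self.features],
                "mode": [f.mode for f in self.features],
            },
            index=pd.Index(self.feature_ids, name="feature_id"),
        )

    def sample_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "injection_order": [s.injection_order for s in self.samples],
                "kind": [s.kind for s in self.samples],
                "pig_id": [s.pig_id for s in self.samples],
                "wound_type": [s.wound_type for s in self.samples],
                "treatment": [s.treatment for s in self.samples],
                "day": [s.day for s in self.samples],
            },
            index=pd.Index(self.sample_ids, name="sample_id"),
        )

    def intensity_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.intensities, index=pd.Index(self.feature_ids, name="feature_id"),
            columns=self.sample_ids,
        )

    # -- transforms -------------------------------------------------------
    def with_intensities(self, intensities: np.ndarray) -> "FeatureTable":
        return FeatureTable(intensities, list(self.features), list(self.samples))

    def subset_features(self, keep: Sequence[str] | np.ndarray) -> "FeatureTable":
        """Subset rows by boolean mask or by feature-id collection (order preserved)."""
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            mask = keep
        else:
            wanted = set(keep)
            mask = np.array([f.feature_id in wanted for f in self.features], dtype=bool)
        feats = [f for f, m in zip(self.features, mask) if m]
        return FeatureTable(self.intensities[mask, :], feats, list(self.samples))

    def subset_samples(self, mask: np.ndarray) -> "FeatureTable":
        mask = np.asarray(mask, dtype=bool)
        samples = [s for s, m in zip(self.samples, mask) if m]
        return FeatureTable(self.intensities[:, mask], list(self.features), samples)

    def split_modes(self) -> dict[str, "FeatureTable"]:
        """Split into per-ionization-mode tables (empty modes omitted)."""
        out: dict[str, FeatureTable] = {}
        for mode in MODES:
            mask = np.array([f.mode == mode for f in self.features], dtype=bool)
            if mask.any():
                out[mode] = self.subset_features(mask)
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return (
            self.features == other.features
            and self.samples == other.samples
            and np.array_equal(self.intensities, other.intensities, equal_nan=True)
        )
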