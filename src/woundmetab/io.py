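"""Readers and writers for on-disk artifacts.

Formats (all UTF-8 text, tab-separated, '.' decimal separator):

* feature table  -- wide TSV (``feature_id  mz  rt  mode  <sample>...``)
  plus a sample-metadata sidecar TSV; empty cells are missing values,
  never zero.
* compound DB    -- TSV with name, formula, kegg_id, fragments
  (semicolon-separated), optional rt and standard columns.
* pathways       -- edge-list TSV (pathway_id, name, node_a, node_b);
  isolated nodes have an empty node_b.
* spectra        -- MGF, one block per feature (TITLE = feature_id).
"""

from __future__ import annotations

import io as _stdio
import math
import re
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml

from .datamodel import (
    KNOWN_ELEMENTS,
    FeatureMeta,
    FeatureTable,
    CompoundRecord,
    ParseError,
    PathwayGraph,
    SampleMeta,
    Spectrum,
    ValidationError,
)

_SAMPLE_COLUMNS = ("sample_id", "injection_order", "kind", "pig_id", "wound_type", "treatment", "day")


def _fmt(value) -> str:
    """Canonical text form: shortest round-tripping repr for floats, '' for missing."""
    if value is None:
        return ""
    if isinstance(value, float):
        if math.isnan(value):
            return ""
        return repr(value)
    return str(value)


def default_samples_path(path: str | Path) -> Path:
    path = Path(path)
    return path.with_name(path.stem + ".samples.tsv")


# ---------------------------------------------------------------------------
# feature table
# ---------------------------------------------------------------------------

def write_feature_table(table: FeatureTable, path: str | Path,
                        samples_path: str | Path | None = None) -> None:
    path = Path(path)
    samples_path = Path(samples_path) if samples_path else default_samples_path(path)
    lines = ["\t".join(["feature_id", "mz", "rt", "mode"] + table.sample_ids)]
    for feat, row in zip(table.features, table.intensities):
        cells = [feat.feature_id, _fmt(feat.mz), _fmt(feat.rt), feat.mode]
        cells.extend(_fmt(float(x)) for x in row)
        lines.append("\t".join(cells))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")

    slines = ["\t".join(_SAMPLE_COLUMNS)]
    for s in table.samples:
        slines.append("\t".join([
            s.sample_id, str(s.injection_order), s.kind,
            _fmt(s.pig_id), _fmt(s.wound_type), _fmt(s.treatment),
            "" if s.day is None else str(s.day),
        ]))
    samples_path.write_text("\n".join(slines) + "\n", encoding="utf-8")


def _read_tsv_rows(path: Path) -> list[list[str]]:
    text = path.read_text(encoding="utf-8")
    rows = [line.split("\t") for line in text.splitlines() if line != ""]
    if not rows:
        raise ParseError(f"{path}: empty file")
    return rows


def read_sample_sidecar(path: str | Path) -> list[SampleMeta]:
    path = Path(path)
    rows = _read_tsv_rows(path)
    header = rows[0]
    if tuple(header) != _SAMPLE_COLUMNS:
        raise ParseError(f"{path}: expected header {_SAMPLE_COLUMNS}, got {tuple(header)}")
    samples = []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise ParseError(f"{path}: line {lineno}: expected {len(header)} columns")
        sid, order, kind, pig, wound, treat, day = row
        try:
            sample = SampleMeta(
                sample_id=sid,
                injection_order=int(order),
                kind=kind,
                pig_id=pig or None,
                wound_type=wound or None,
                treatment=treat or None,
                day=int(day) if day else None,
            )
            sample.validate()
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path}: line {lineno}: {exc}") from exc
        samples.append(sample)
    return samples


def read_feature_table(path: str | Path, samples_path: str | Path | None = None,
                       dialect: str = "wide_tsv") -> FeatureTable:
    """Read a wide-TSV feature matrix plus its sample-metadata sidecar."""
    if dialect != "wide_tsv":
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    samples_path = Path(samples_path) if samples_path else default_samples_path(path)
    samples = {s.sample_id: s for s in read_sample_sidecar(samples_path)}

    rows = _read_tsv_rows(path)
    header = rows[0]
    if header[:4] != ["feature_id", "mz", "rt", "mode"]:
        raise ParseError(f"{path}: expected columns feature_id, mz, rt, mode first")
    sample_ids = header[4:]
    missing = [sid for sid in sample_ids if sid not in samples]
    if missing:
        raise ValidationError(
            f"{path}: samples present in matrix but absent from sidecar: {missing}"
        )
    features: list[FeatureMeta] = []
    values: list[list[float]] = []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise ParseError(f"{path}: line {lineno}: expected {len(header)} columns")
        try:
            feat = FeatureMeta(row[0], float(row[1]), float(row[2]), row[3])
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from exc
        features.append(feat)
        values.append([float(c) if c != "" else np.nan for c in row[4:]])
    return FeatureTable(
        np.array(values, dtype=float).reshape(len(features), len(sample_ids)),
        features,
        [samples[sid] for sid in sample_ids],
    )


# ---------------------------------------------------------------------------
# compound database
# ---------------------------------------------------------------------------

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> dict[str, int]:
    """Parse e.g. 'C4H6N4O3' into {'C': 4, 'H': 6, 'N': 4, 'O': 3}."""
    if not text:
        raise ParseError("empty formula")
    formula: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise ParseError(f"formula {text!r}: unparseable at {text[pos:]!r}")
        el = m.group(1)
        if el not in KNOWN_ELEMENTS:
            raise ParseError(f"formula {text!r}: unknown element symbol {el!r}")
        count = int(m.group(2)) if m.group(2) else 1
        formula[el] = formula.get(el, 0) + count
        pos = m.end()
    if pos != len(text):
        raise ParseError(f"formula {text!r}: unparseable at {text[pos:]!r}")
    return formula


def read_compound_db(path: str | Path) -> list[CompoundRecord]:
    path = Path(path)
    rows = _read_tsv_rows(path)
    header = rows[0]
    required = ["name", "formula", "kegg_id", "fragments"]
    if header[: len(required)] != required:
        raise ParseError(f"{path}: expected leading columns {required}")
    col = {name: i for i, name in enumerate(header)}
    records = []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise ParseError(f"{path}: line {lineno}: expected {len(header)} columns")
        try:
            formula = parse_formula(row[col["formula"]])
        except ParseError as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from exc
        kegg = row[col["kegg_id"]]
        frag_text = row[col["fragments"]]
        fragments = [float(x) for x in frag_text.split(";") if x] if frag_text else None
        rt_text = row[col["rt"]] if "rt" in col else ""
        standard_text = row[col["standard"]] if "standard" in col else ""
        rec = CompoundRecord(
            name=row[col["name"]],
            formula=formula,
            kegg_id=kegg if kegg not in ("", "-", "#N/A") else None,
            fragments=fragments,
            rt=float(rt_text) if rt_text else None,
            is_standard=standard_text in ("1", "true", "True", "yes"),
        )
        try:
            rec.validate()
        except ValidationError as exc:
            raise ValidationError(f"{path}: line {lineno}: {exc}") from exc
        records.append(rec)
    return records


def write_compound_db(records: Iterable[CompoundRecord], path: str | Path) -> None:
    path = Path(path)
    lines = ["\t".join(["name", "formula", "kegg_id", "fragments", "rt", "standard"])]
    for rec in records:
        formula = "".join(
            f"{el}{n if n > 1 else ''}" for el, n in rec.formula.items()
        )
        fragments = ";".join(_fmt(f) for f in rec.fragments) if rec.fragments else ""
        lines.append("\t".join([
            rec.name, formula, rec.kegg_id or "", fragments,
            _fmt(rec.rt), "1" if rec.is_standard else "",
        ]))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# pathways
# ---------------------------------------------------------------------------

def read_pathways(path: str | Path) -> list[PathwayGraph]:
    path = Path(path)
    rows = _read_tsv_rows(path)
    header = rows[0]
    if header != ["pathway_id", "name", "node_a", "node_b"]:
        raise ParseError(f"{path}: expected header pathway_id, name, node_a, node_b")
    graphs: dict[str, PathwayGraph] = {}
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != 4:
            raise ParseError(f"{path}: line {lineno}: expected 4 columns")
        pid, name, a, b = row
        if not a:
            raise ParseError(f"{path}: line {lineno}: empty node_a")
        graph = graphs.setdefault(pid, PathwayGraph(pathway_id=pid, name=name))
        graph.nodes.add(a)
        if b:
            if a == b:
                raise ValidationError(f"{path}: line {lineno}: self-loop edge {a}")
            graph.nodes.add(b)
            graph.edges.add(frozenset((a, b)))
    for graph in graphs.values():
        graph.validate()
    return list(graphs.values())


def write_pathways(graphs: Iterable[PathwayGraph], path: str | Path) -> None:
    path = Path(path)
    lines = ["\t".join(["pathway_id", "name", "node_a", "node_b"])]
    for g in graphs:
        in_edges = {n for e in g.edges for n in e}
        for edge in sorted(tuple(sorted(e)) for e in g.edges):
            lines.append("\t".join([g.pathway_id, g.name, edge[0], edge[1]]))
        for node in sorted(g.nodes - in_edges):
            lines.append("\t".join([g.pathway_id, g.name, node, ""]))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# MS/MS spectra (MGF)
# ---------------------------------------------------------------------------

def read_spectra(path: str | Path) -> dict[str, Spectrum]:
    """Read an MGF file into a feature_id -> Spectrum map (TITLE = feature_id)."""
    from pyteomics import mgf

    path = Path(path)
    text = path.read_text(encoding="utf-8")
    n_begin = text.count("BEGIN IONS")
    n_end = text.count("END IONS")
    if n_begin != n_end:
        raise ParseError(
            f"{path}: unbalanced MGF blocks ({n_begin} BEGIN IONS vs {n_end} END IONS)"
        )
    spectra: dict[str, Spectrum] = {}
    if n_begin == 0:
        return spectra
    with mgf.MGF(_stdio.StringIO(text)) as reader:
        for entry in reader:
            title = entry["params"].get("title")
            if not title:
                raise ParseError(f"{path}: MGF block without TITLE")
            spectra[str(title)] = Spectrum(entry["m/z array"], entry["intensity array"])
    return spectra


def write_spectra(spectra: dict[str, Spectrum], path: str | Path) -> None:
    lines = []
    for fid, spec in spectra.items():
        lines.append("BEGIN IONS")
        lines.append(f"TITLE={fid}")
        for mz, inten in zip(spec.mz, spec.intensity):
            lines.append(f"{_fmt(float(mz))} {_fmt(float(inten))}")
        lines.append("END IONS")
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------

def read_yaml(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ParseError(f"{path}: expected a mapping at top level")
    return data
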