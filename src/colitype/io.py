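"""TSV readers and writers for every pipeline table.

All interchange formats are plain UTF-8 tab-separated files with
case-sensitive headers (the data are small tabular counts; no binary
format is warranted).  Readers validate each record and report errors
with file, line and column; floats are written with ``repr`` so that a
write-then-read round trip is lossless.

Column dialects (all in this one module):

* qPCR counts:   sample_id, total_cfu, b1_cfu, b2_cfu, d_cfu, yjaa_cfu
* host metadata: host_id, species, habitat, diet
* strain panel:  strain_id, origin_group, <the 20 VF gene columns>,
                 optional b2_subgroup, o_type, colicin_phage
* profiles:      sample_id, total_cfu, p_a, p_a1, p_a0, p_b1, p_b2, p_d,
                 ecoli_present, detected_<g>, warnings (' | '-joined)
* phenotypes:    sample_id, category_<g>, cfu_class, diversity_class,
                 n_groups_detected, enterocolitype
* indicator:     row label column 'id' + one column per variable
"""

from __future__ import annotations

import csv
import math
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .classify import IndicatorTable, SamplePhenotype
from .hosts import HostProfile
from .quantify import PHYLOGROUPS, PhylogroupProfile, QPCRCounts
from .virulence import VF_GENES, StrainVFProfile


class TableFormatError(ValueError):
    """A malformed input table; the message cites file, line and column."""


def _read_rows(path: str | Path, required: Sequence[str]) -> tuple[list[str], list[tuple[int, dict]]]:
    path = Path(path)
    with open(path, encoding="utf-8", newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise TableFormatError(f"{path}: file is empty") from None
        missing = [c for c in required if c not in header]
        if missing:
            raise TableFormatError(
                f"{path}, line 1: missing required column(s) {missing}"
            )
        rows = []
        for lineno, raw in enumerate(reader, start=2):
            if not raw or (len(raw) == 1 and raw[0] == ""):
                continue
            if len(raw) != len(header):
                raise TableFormatError(
                    f"{path}, line {lineno}: expected {len(header)} fields, "
                    f"got {len(raw)}"
                )
            rows.append((lineno, dict(zip(header, raw))))
    return header, rows


def _parse_float(value: str, path, lineno: int, column: str) -> float:
    try:
        out = float(value)
    except ValueError:
        raise TableFormatError(
            f"{path}, line {lineno}, column {column!r}: "
            f"not a number: {value!r}"
        ) from None
    if not math.isfinite(out):
        raise TableFormatError(
            f"{path}, line {lineno}, column {column!r}: non-finite value"
        )
    return out


def _parse_count(value: str, path, lineno: int, column: str) -> float:
    out = _parse_float(value, path, lineno, column)
    if out < 0:
        raise TableFormatError(
            f"{path}, line {lineno}, column {column!r}: "
            f"negative CFU count {out!r}"
        )
    return out


_QPCR_COLUMNS = ("sample_id", "total_cfu", "b1_cfu", "b2_cfu", "d_cfu", "yjaa_cfu")


def read_qpcr_table(path: str | Path) -> list[QPCRCounts]:
    _, rows = _read_rows(path, _QPCR_COLUMNS)
    records = []
    for lineno, row in rows:
        try:
            records.append(
                QPCRCounts(
                    sample_id=row["sample_id"],
                    **{
                        c: _parse_count(row[c], path, lineno, c)
                        for c in _QPCR_COLUMNS[1:]
                    },
                )
            )
        except ValueError as exc:
            if isinstance(exc, TableFormatError):
                raise
            raise TableFormatError(f"{path}, line {lineno}: {exc}") from None
    return records


def write_qpcr_table(records: Iterable[QPCRCounts], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(_QPCR_COLUMNS)
        for rec in records:
            writer.writerow(
                [rec.sample_id]
                + [repr(getattr(rec, c)) for c in _QPCR_COLUMNS[1:]]
            )


_HOST_COLUMNS = ("host_id", "species", "habitat", "diet")


def read_metadata(path: str | Path) -> list[HostProfile]:
    _, rows = _read_rows(path, _HOST_COLUMNS)
    hosts = []
    for lineno, row in rows:
        try:
            hosts.append(HostProfile(**{c: row[c] for c in _HOST_COLUMNS}))
        except ValueError as exc:
            raise TableFormatError(f"{path}, line {lineno}: {exc}") from None
    return hosts


def write_metadata(hosts: Iterable[HostProfile], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(_HOST_COLUMNS)
        for host in hosts:
            writer.writerow([getattr(host, c) for c in _HOST_COLUMNS])


_STRAIN_OPTIONAL = ("b2_subgroup", "o_type", "colicin_phage")


def read_strain_table(path: str | Path) -> list[StrainVFProfile]:
    header, rows = _read_rows(path, ("strain_id", "origin_group"))
    missing_genes = [g for g in VF_GENES if g not in header]
    if missing_genes:
        raise TableFormatError(
            f"{path}, line 1: missing virulence gene column(s) {missing_genes}"
        )
    strains = []
    for lineno, row in rows:
        genes = {}
        for gene in VF_GENES:
            value = row[gene]
            if value not in ("0", "1"):
                raise TableFormatError(
                    f"{path}, line {lineno}, column {gene!r}: "
                    f"gene values must be 0 or 1, got {value!r}"
                )
            genes[gene] = int(value)
        optional: dict = {}
        if "b2_subgroup" in header and row["b2_subgroup"] != "":
            optional["b2_subgroup"] = row["b2_subgroup"]
        if "o_type" in header and row["o_type"] != "":
            optional["o_type"] = row["o_type"]
        if "colicin_phage" in header and row["colicin_phage"] != "":
            value = row["colicin_phage"]
            if value not in ("0", "1"):
                raise TableFormatError(
                    f"{path}, line {lineno}, column 'colicin_phage': "
                    f"must be 0 or 1, got {value!r}"
                )
            optional["colicin_phage"] = bool(int(value))
        try:
            strains.append(
                StrainVFProfile(
                    strain_id=row["strain_id"],
                    origin_group=row["origin_group"],
                    genes=genes,
                    **optional,
                )
            )
        except ValueError as exc:
            raise TableFormatError(f"{path}, line {lineno}: {exc}") from None
    return strains


def write_strain_table(strains: Iterable[StrainVFProfile], path: str | Path) -> None:
    columns = ("strain_id", "origin_group", *VF_GENES, *_STRAIN_OPTIONAL)
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(columns)
        for s in strains:
            writer.writerow(
                [s.strain_id, s.origin_group]
                + [s.genes[g] for g in VF_GENES]
                + [
                    s.b2_subgroup if s.b2_subgroup is not None else "",
                    s.o_type if s.o_type is not None else "",
                    "" if s.colicin_phage is None else int(s.colicin_phage),
                ]
            )


_PROFILE_COLUMNS = (
    "sample_id", "total_cfu",
    "p_a", "p_a1", "p_a0", "p_b1", "p_b2", "p_d",
    "ecoli_present",
    "detected_a", "detected_b1", "detected_b2", "detected_d",
    "warnings",
)


def write_profiles(
    profiles: Iterable[tuple[PhylogroupProfile, float]], path: str | Path
) -> None:
    """Write (profile, total_cfu) pairs; total CFU travels along so the
    classification stage can run from this file alone."""
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(_PROFILE_COLUMNS)
        for profile, total_cfu in profiles:
            detected = profile.detected or {}
            writer.writerow(
                [
                    profile.sample_id,
                    repr(float(total_cfu)),
                    *(
                        repr(float(getattr(profile, f)))
                        for f in ("p_a", "p_a1", "p_a0", "p_b1", "p_b2", "p_d")
                    ),
                    int(profile.ecoli_present),
                    *(int(bool(detected.get(g, False))) for g in PHYLOGROUPS),
                    " | ".join(profile.warnings),
                ]
            )


def read_profiles(path: str | Path) -> list[tuple[PhylogroupProfile, float]]:
    _, rows = _read_rows(path, _PROFILE_COLUMNS)
    out = []
    for lineno, row in rows:
        present = row["ecoli_present"] == "1"
        profile = PhylogroupProfile(
            sample_id=row["sample_id"],
            **{
                f: _parse_float(row[f], path, lineno, f)
                for f in ("p_a", "p_a1", "p_a0", "p_b1", "p_b2", "p_d")
            },
            ecoli_present=present,
            detected={
                g: row[f"detected_{g.lower()}"] == "1" for g in PHYLOGROUPS
            },
            warnings=tuple(w for w in row["warnings"].split(" | ") if w),
        )
        out.append((profile, _parse_float(row["total_cfu"], path, lineno, "total_cfu")))
    return out


_PHENOTYPE_COLUMNS = (
    "sample_id",
    "category_a", "category_b1", "category_b2", "category_d",
    "cfu_class", "diversity_class", "n_groups_detected", "enterocolitype",
)


def write_phenotypes(phenotypes: Iterable[SamplePhenotype], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(_PHENOTYPE_COLUMNS)
        for ph in phenotypes:
            writer.writerow(
                [
                    ph.sample_id,
                    *(ph.category[g] for g in PHYLOGROUPS),
                    ph.cfu_class,
                    ph.diversity_class,
                    ph.n_groups_detected,
                    ph.enterocolitype,
                ]
            )


def read_phenotypes(path: str | Path) -> list[SamplePhenotype]:
    _, rows = _read_rows(path, _PHENOTYPE_COLUMNS)
    out = []
    for lineno, row in rows:
        try:
            out.append(
                SamplePhenotype(
                    sample_id=row["sample_id"],
                    category={
                        g: row[f"category_{g.lower()}"] for g in PHYLOGROUPS
                    },
                    cfu_class=row["cfu_class"],
                    diversity_class=row["diversity_class"],
                    n_groups_detected=int(row["n_groups_detected"]),
                    enterocolitype=row["enterocolitype"],
                )
            )
        except ValueError as exc:
            raise TableFormatError(f"{path}, line {lineno}: {exc}") from None
    return out


def write_indicator(table: IndicatorTable, path: str | Path) -> None:
    frame = table.to_frame()
    frame.index.name = "id"
    frame.to_csv(path, sep="\t", lineterminator="\n")


def read_indicator(path: str | Path) -> IndicatorTable:
    frame = pd.read_csv(path, sep="\t", index_col="id")
    return IndicatorTable.from_frame(frame)
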