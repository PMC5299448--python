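"""Tabular readers/writers for every artifact in the workflow.

All files are plain TSV (tab-separated, UTF-8, Unix newlines).  Count
tables are accession x sample matrices with ``accession``, ``length_aa``,
``description`` leading columns; sample metadata (patient pairing and
condition) lives in a sidecar TSV rather than being encoded in column
names.  Blank count cells mean the protein was not identified in that
sample (count 0).
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import pandas as pd

from .models import (
    AbundanceProfile,
    ClassLabel,
    Condition,
    DifferentialRecord,
    GeneList,
    HousekeepingReference,
    POCDefinition,
    POCResult,
    ProteinEntry,
    QCReport,
    SpectralCountProfile,
    TestUsed,
)

logger = logging.getLogger(__name__)

_COUNT_META_COLS = ("accession", "length_aa", "description")

DIFFERENTIAL_COLUMNS = [
    "accession",
    "mean_ppm_tumor",
    "mean_ppm_adjacent",
    "ratio",
    "p_value",
    "test_used",
    "n_detected_tumor",
    "n_detected_adjacent",
    "signature_flag",
    "class_label",
    "q_value",
]


def read_sample_metadata(path: str | Path) -> dict[str, tuple[str, Condition]]:
    """Read the sidecar mapping sample_id -> (patient_id, condition)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "patient_id", "condition"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: metadata must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    meta: dict[str, tuple[str, Condition]] = {}
    for row in df.itertuples(index=False):
        if row.sample_id in meta:
            raise ValueError(f"{path}: duplicate sample_id {row.sample_id!r}")
        meta[row.sample_id] = (row.patient_id, Condition.parse(row.condition))
    return meta


def read_count_table(
    path: str | Path, metadata_path: str | Path
) -> tuple[list[ProteinEntry], list[SpectralCountProfile]]:
    """Read a protein x sample spectrum-count matrix plus its metadata sidecar.

    Returns the protein table and one :class:`SpectralCountProfile` per
    sample column.  Missing/blank cells parse as count 0.  Duplicate
    accessions, negative or non-integer counts, and samples missing from the
    sidecar are hard errors.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"accession": str, "description": str})
    for col in ("accession", "length_aa"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    dupes = df["accession"][df["accession"].duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"{path}: duplicate accession rows: {', '.join(dupes)}")

    if "description" not in df.columns:
        df["description"] = ""
    df["description"] = df["description"].fillna("")

    proteins = [
        ProteinEntry(
            accession=row.accession,
            length_aa=int(row.length_aa),
            description=row.description,
        )
        for row in df.itertuples(index=False)
    ]

    meta = read_sample_metadata(metadata_path)
    sample_cols = [c for c in df.columns if c not in _COUNT_META_COLS]
    if not sample_cols:
        raise ValueError(f"{path}: no sample columns found")

    profiles: list[SpectralCountProfile] = []
    for col in sample_cols:
        if col not in meta:
            raise ValueError(f"{path}: sample column {col!r} absent from metadata sidecar")
        patient_id, condition = meta[col]
        counts: dict[str, int] = {}
        for acc, raw in zip(df["accession"], df[col]):
            if pd.isna(raw) or (isinstance(raw, str) and raw.strip() == ""):
                val = 0
            else:
                fval = float(raw)
                if not fval.is_integer():
                    raise ValueError(
                        f"{path}: non-integer count {raw!r} for {acc} in column {col!r}"
                    )
                val = int(fval)
            if val < 0:
                raise ValueError(
                    f"{path}: negative count {val} for {acc} in column {col!r}"
                )
            counts[acc] = val
        profiles.append(
            SpectralCountProfile(
                sample_id=col, patient_id=patient_id, condition=condition, counts=counts
            )
        )
    return proteins, profiles


def write_count_table(
    proteins: list[ProteinEntry],
    profiles: list[SpectralCountProfile],
    path: str | Path,
    metadata_path: str | Path | None = None,
) -> None:
    """Write a count matrix and (optionally) its metadata sidecar."""
    data: dict[str, list] = {
        "accession": [p.accession for p in proteins],
        "length_aa": [p.length_aa for p in proteins],
        "description": [p.description for p in proteins],
    }
    for prof in profiles:
        data[prof.sample_id] = [prof.counts.get(p.accession, 0) for p in proteins]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, lineterminator="\n")
    if metadata_path is not None:
        write_sample_metadata(profiles, metadata_path)


def write_sample_metadata(
    profiles: list[SpectralCountProfile] | list[AbundanceProfile],
    path: str | Path,
) -> None:
    pd.DataFrame(
        {
            "sample_id": [p.sample_id for p in profiles],
            "patient_id": [p.patient_id for p in profiles],
            "condition": [p.condition.value for p in profiles],
        }
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_reference_list(path: str | Path) -> HousekeepingReference:
    """Read a grouped reference list TSV (columns: group_name, accession).

    A member repeated within one group is deduplicated with a warning; the
    same accession in two groups is a hard error (group membership must be
    unambiguous).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise ValueError(f"{path}: reference list is empty")
    if not {"group_name", "accession"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns group_name, accession")
    groups: dict[str, set[str]] = {}
    owner: dict[str, str] = {}
    for row in df.itertuples(index=False):
        g, acc = row.group_name, row.accession
        members = groups.setdefault(g, set())
        if acc in members:
            logger.warning("%s: %s repeated within group %s; deduplicated", path, acc, g)
            continue
        if acc in owner:
            raise ValueError(
                f"{path}: accession {acc} appears in groups {owner[acc]!r} and {g!r}"
            )
        members.add(acc)
        owner[acc] = g
    return HousekeepingReference(groups=groups)


def write_reference_list(reference: HousekeepingReference, path: str | Path) -> None:
    rows = [
        {"group_name": g, "accession": acc}
        for g, members in reference.groups.items()
        for acc in sorted(members)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_gene_list(path: str | Path, name: str | None = None) -> GeneList:
    """Read a gene list: one symbol/accession per line; name defaults to the stem."""
    path = Path(path)
    members = [
        line.strip()
        for line in path.read_text(encoding="utf-8").splitlines()
        if line.strip()
    ]
    return GeneList(name=name or path.stem, members=frozenset(members))


def read_poc_definitions(path: str | Path) -> list[POCDefinition]:
    """Read POC definitions TSV (columns: pathway, chain, accession)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"pathway", "chain", "accession"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns pathway, chain, accession")
    grouped: dict[tuple[str, str], set[str]] = {}
    for row in df.itertuples(index=False):
        grouped.setdefault((row.pathway, row.chain), set()).add(row.accession)
    return [
        POCDefinition(pathway=p, chain=c, members=frozenset(m))
        for (p, c), m in grouped.items()
    ]


def write_poc_definitions(pocs: list[POCDefinition], path: str | Path) -> None:
    rows = [
        {"pathway": poc.pathway, "chain": poc.chain, "accession": acc}
        for poc in pocs
        for acc in sorted(poc.members)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def _fmt(x: float) -> str:
    """Format a float with 6 significant digits (NaN-safe)."""
    if isinstance(x, float) and math.isnan(x):
        return "nan"
    return f"{x:.6g}"


def write_differential_table(records: list[DifferentialRecord], path: str | Path) -> None:
    """Write differential records as TSV, floats at 6 significant digits.

    Column order is fixed so tables diff cleanly between runs; the table
    round-trips losslessly at the written precision via
    :func:`read_differential_table`.
    """
    if not records:
        raise ValueError("cannot write an empty differential table")
    rows = [
        {
            "accession": r.accession,
            "mean_ppm_tumor": _fmt(r.mean_ppm_tumor),
            "mean_ppm_adjacent": _fmt(r.mean_ppm_adjacent),
            "ratio": _fmt(r.ratio),
            "p_value": _fmt(r.p_value),
            "test_used": r.test_used.value,
            "n_detected_tumor": r.n_detected_tumor,
            "n_detected_adjacent": r.n_detected_adjacent,
            "signature_flag": r.signature_flag,
            "class_label": r.class_label.value,
            "q_value": _fmt(r.q_value),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=DIFFERENTIAL_COLUMNS).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def read_differential_table(path: str | Path) -> list[DifferentialRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"accession": str})
    return [
        DifferentialRecord(
            accession=row.accession,
            mean_ppm_tumor=float(row.mean_ppm_tumor),
            mean_ppm_adjacent=float(row.mean_ppm_adjacent),
            ratio=float(row.ratio),
            p_value=float(row.p_value),
            test_used=TestUsed(row.test_used),
            n_detected_tumor=int(row.n_detected_tumor),
            n_detected_adjacent=int(row.n_detected_adjacent),
            class_label=ClassLabel(row.class_label),
            signature_flag=bool(row.signature_flag),
            q_value=float(row.q_value),
        )
        for row in df.itertuples(index=False)
    ]


def write_abundance_matrix(
    proteins: list[ProteinEntry],
    profiles: list[AbundanceProfile],
    path: str | Path,
    metadata_path: str | Path | None = None,
) -> None:
    """Write an accession x sample ppm matrix (same layout as count tables)."""
    data: dict[str, list] = {"accession": [p.accession for p in proteins]}
    for prof in profiles:
        data[prof.sample_id] = [prof.ppm.get(p.accession, 0.0) for p in proteins]
    pd.DataFrame(data).to_csv(
        path, sep="\t", index=False, lineterminator="\n", float_format="%.6g"
    )
    if metadata_path is not None:
        write_sample_metadata(profiles, metadata_path)


def write_qc_reports(reports: list[QCReport], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "score": _fmt(r.score),
                "n_found": r.n_found,
                "n_reference": r.n_reference,
                "n_missing": len(r.missing),
            }
            for r in reports
        ]
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_group_coverage(reports: list[QCReport], path: str | Path) -> None:
    rows = [
        {"sample_id": r.sample_id, "group_name": g, "coverage": _fmt(c)}
        for r in reports
        for g, c in r.per_group_coverage.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_poc_results(results: list[POCResult], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "pathway": r.pathway,
                "chain": r.chain,
                "mean_sum_ppm_tumor": _fmt(r.mean_sum_ppm_tumor),
                "mean_sum_ppm_adjacent": _fmt(r.mean_sum_ppm_adjacent),
                "percent_change": _fmt(r.percent_change),
                "p_value": _fmt(r.p_value),
            }
            for r in results
        ]
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")
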