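"""File-format adapters: FASTA via Biopython, tables via pandas."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .gcms import Chromatogram
from .isotopes import IonTable
from .kinetics import RateObservation
from .motifs import CandidateReport, ProteinRecord, sanitize_residues


def read_fasta(path: str | Path, *, lenient: bool = False) -> list[ProteinRecord]:
    """Read a multi-record (possibly line-wrapped) protein FASTA.

    Sequences with gaps or stop characters are rejected; ambiguity codes
    raise in strict mode and are dropped with ``lenient=True``.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = sanitize_residues(str(rec.seq), seq_id=rec.id, lenient=lenient)
        records.append(ProteinRecord(id=rec.id, residues=residues, description=rec.description))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: list[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def reports_to_frame(reports: list[CandidateReport]) -> pd.DataFrame:
    """Flatten classification reports to the hits/report table.

    One row per motif hit (or a single hit-less row for negatives) with
    columns seq_id, start, matched, relative_position, anchors_ok, verdict.
    """
    rows = []
    for rep in reports:
        anchors_ok = all(rep.anchors_ok.values()) if rep.anchors_ok else False
        if rep.hits:
            for h in rep.hits:
                rows.append(
                    (rep.seq_id, h.start, h.matched, h.relative_position, anchors_ok, rep.verdict)
                )
        else:
            rows.append((rep.seq_id, pd.NA, "", pd.NA, anchors_ok, rep.verdict))
    return pd.DataFrame(
        rows, columns=["seq_id", "start", "matched", "relative_position", "anchors_ok", "verdict"]
    )


def write_reports_tsv(reports: list[CandidateReport], path: str | Path) -> None:
    reports_to_frame(reports).to_csv(path, sep="\t", index=False)


def read_plate_csv(path: str | Path) -> pd.DataFrame:
    """Tidy plate table: well, role (standard|sample), concentration, response."""
    df = pd.read_csv(path)
    required = {"well", "role", "concentration", "response"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")
    bad_roles = set(df["role"]) - {"standard", "sample"}
    if bad_roles:
        raise ValueError(f"unknown plate roles: {sorted(bad_roles)}")
    return df


def read_ion_csv(path: str | Path) -> dict[str, IonTable]:
    """Long-format ion areas (sample_id, mz, area) -> IonTable per sample."""
    df = pd.read_csv(path)
    required = {"sample_id", "mz", "area"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ion table missing columns: {sorted(missing)}")
    tables: dict[str, IonTable] = {}
    for sample_id, grp in df.groupby("sample_id", sort=False):
        areas = {int(mz): float(a) for mz, a in zip(grp["mz"], grp["area"])}
        tables[str(sample_id)] = IonTable(
            **{f"area{mz}": areas.get(mz, 0.0) for mz in (28, 29, 30, 44, 45, 46)}
        )
    return tables


def read_chromatogram_csv(path: str | Path) -> Chromatogram:
    """Two-column trace: time_min, intensity."""
    df = pd.read_csv(path)
    cols = list(df.columns)
    if len(cols) < 2:
        raise ValueError("chromatogram CSV needs time and intensity columns")
    return Chromatogram(time_min=df[cols[0]].to_numpy(), intensity=df[cols[1]].to_numpy())


def read_rates_csv(path: str | Path) -> list[RateObservation]:
    """Initial-rate table: substrate_uM, rate_uM_per_s."""
    df = pd.read_csv(path)
    required = {"substrate_uM", "rate_uM_per_s"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"rate table missing columns: {sorted(missing)}")
    return [
        RateObservation(substrate_uM=float(s), rate_uM_per_s=float(v))
        for s, v in zip(df["substrate_uM"], df["rate_uM_per_s"])
    ]
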