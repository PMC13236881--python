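"""Delimited-table readers/writers, FASTA annotation and report formatting.

Interchange format is comma-delimited text with unit-bearing column names
(``As_total_uM``, ``Q_ug_per_g``, ...).  Scalar metadata that does not fit a
column (total site concentrations, labels) travels in ``# key = value``
comment lines at the top of the file; readers parse them and writers emit
them, so write→read round-trips are exact.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .datasets import CompetitiveDataset, IsothermDataset, KineticsDataset, LoadingDataset
from .errors import ParseError
from .particles import ARSENIC, AdsorbentSuspension, LigandSpec

ISOTHERM_COLUMNS = ["label", "As_total_uM", "As_free_uM", "As_bound_uM"]
KINETICS_COLUMNS = ["t_h", "Q_ug_per_g"]
COMPETITION_COLUMNS = ["As_total_uM", "R_bound_uM"]
LOADING_COLUMNS = ["sphere_conc_uM", "protein_bound_uM"]
INTERFERENCE_COLUMNS = ["adsorbent", "metal", "Q_with", "Q_without"]
SUSPENSION_COLUMNS = ["label", "mass_conc_g_per_L", "particles_per_gram"]

_NUCLEOTIDE = set("ACGTUN")


def _read_header_block(path: Path) -> dict[str, str]:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                key, _, value = line.lstrip("#").partition("=")
                meta[key.strip()] = value.strip()
    return meta


def _read_table(path, required: list[str], numeric: list[str],
                non_negative: list[str] | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file does not exist")
    df = pd.read_csv(path, comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")
    for col in numeric:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ParseError(
                f"{path}: row {row + 2}, column {col!r}: "
                f"{df[col][row]!r} is not numeric"
            )
        if converted.isna().any():
            row = int(converted.isna().idxmax())
            raise ParseError(f"{path}: row {row + 2}, column {col!r}: missing value")
        df[col] = converted
    for col in non_negative or []:
        if (df[col] < 0).any():
            row = int((df[col] < 0).idxmax())
            raise ParseError(
                f"{path}: row {row + 2}, column {col!r}: negative value {df[col][row]}"
            )
    return df


def read_suspensions(path) -> dict[str, AdsorbentSuspension]:
    """Read suspension metadata keyed by label."""
    df = _read_table(path, SUSPENSION_COLUMNS,
                     numeric=["mass_conc_g_per_L", "particles_per_gram"],
                     non_negative=["mass_conc_g_per_L", "particles_per_gram"])
    return {
        str(row.label): AdsorbentSuspension(
            mass_conc=row.mass_conc_g_per_L,
            particles_per_gram=row.particles_per_gram,
            label=str(row.label),
        )
        for row in df.itertuples()
    }


def write_suspensions(suspensions: dict[str, AdsorbentSuspension], path) -> None:
    rows = [{"label": s.label or label, "mass_conc_g_per_L": s.mass_conc,
             "particles_per_gram": s.particles_per_gram}
            for label, s in suspensions.items()]
    pd.DataFrame(rows, columns=SUSPENSION_COLUMNS).to_csv(path, index=False)


def read_isotherm(path, suspension: AdsorbentSuspension,
                  ligand: LigandSpec = ARSENIC) -> IsothermDataset:
    """Read an isotherm table; mass-balance closure is validated on construction."""
    numeric = ["As_total_uM", "As_free_uM", "As_bound_uM"]
    df = _read_table(path, ISOTHERM_COLUMNS, numeric=numeric, non_negative=numeric)
    labels = df["label"].astype(str).unique()
    return IsothermDataset(
        total=df["As_total_uM"].to_numpy(),
        free=df["As_free_uM"].to_numpy(),
        bound=df["As_bound_uM"].to_numpy(),
        suspension=suspension,
        ligand=ligand,
        label=labels[0] if len(labels) == 1 else ",".join(labels),
    )


def write_isotherm(ds: IsothermDataset, path) -> None:
    pd.DataFrame({
        "label": ds.label or "isotherm",
        "As_total_uM": ds.total,
        "As_free_uM": ds.free,
        "As_bound_uM": ds.bound,
    }).to_csv(path, index=False, float_format="%.10g")


def read_kinetics(path) -> KineticsDataset:
    meta = _read_header_block(Path(path))
    df = _read_table(path, KINETICS_COLUMNS, numeric=KINETICS_COLUMNS,
                     non_negative=KINETICS_COLUMNS)
    q_e = float(meta["Q_e_observed_ug_per_g"]) if "Q_e_observed_ug_per_g" in meta else None
    return KineticsDataset(t=df["t_h"].to_numpy(), q_t=df["Q_ug_per_g"].to_numpy(),
                           q_e_observed=q_e, label=meta.get("label", ""))


def write_kinetics(ds: KineticsDataset, path) -> None:
    with open(path, "w") as fh:
        if ds.label:
            fh.write(f"# label = {ds.label}\n")
        if ds.q_e_observed is not None:
            fh.write(f"# Q_e_observed_ug_per_g = {ds.q_e_observed:.10g}\n")
        pd.DataFrame({"t_h": ds.t, "Q_ug_per_g": ds.q_t}).to_csv(
            fh, index=False, float_format="%.10g")


def read_competition(path) -> CompetitiveDataset:
    """Read a competition table; R_total/P_total come from the header block."""
    path = Path(path)
    meta = _read_header_block(path)
    for key in ("R_total_uM", "P_total_uM"):
        if key not in meta:
            raise ParseError(f"{path}: header block lacks '# {key} = ...'")
    df = _read_table(path, COMPETITION_COLUMNS, numeric=COMPETITION_COLUMNS,
                     non_negative=COMPETITION_COLUMNS)
    return CompetitiveDataset(
        as_total=df["As_total_uM"].to_numpy(),
        r_bound=df["R_bound_uM"].to_numpy(),
        r_total=float(meta["R_total_uM"]),
        p_total=float(meta["P_total_uM"]),
        label_r=meta.get("R_label", "R"),
        label_p=meta.get("P_label", "P"),
    )


def write_competition(ds: CompetitiveDataset, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# R_total_uM = {ds.r_total:.10g}\n")
        fh.write(f"# P_total_uM = {ds.p_total:.10g}\n")
        fh.write(f"# R_label = {ds.label_r}\n")
        fh.write(f"# P_label = {ds.label_p}\n")
        pd.DataFrame({"As_total_uM": ds.as_total, "R_bound_uM": ds.r_bound}).to_csv(
            fh, index=False, float_format="%.10g")


def read_loading(path) -> LoadingDataset:
    path = Path(path)
    meta = _read_header_block(path)
    if "protein_total_uM" not in meta:
        raise ParseError(f"{path}: header block lacks '# protein_total_uM = ...'")
    df = _read_table(path, LOADING_COLUMNS, numeric=LOADING_COLUMNS,
                     non_negative=LOADING_COLUMNS)
    return LoadingDataset(
        sphere_conc=df["sphere_conc_uM"].to_numpy(),
        protein_bound=df["protein_bound_uM"].to_numpy(),
        protein_total=float(meta["protein_total_uM"]),
        label=meta.get("label", ""),
    )


def write_loading(ds: LoadingDataset, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# protein_total_uM = {ds.protein_total:.10g}\n")
        if ds.label:
            fh.write(f"# label = {ds.label}\n")
        pd.DataFrame({"sphere_conc_uM": ds.sphere_conc,
                      "protein_bound_uM": ds.protein_bound}).to_csv(
            fh, index=False, float_format="%.10g")


def read_interference(path) -> list[tuple[str, str, float, float]]:
    df = _read_table(path, INTERFERENCE_COLUMNS, numeric=["Q_with", "Q_without"],
                     non_negative=["Q_with"])
    return [(str(r.adsorbent), str(r.metal), float(r.Q_with), float(r.Q_without))
            for r in df.itertuples()]


@dataclass(frozen=True)
class SequenceAnnotation:
    """Cysteine annotation of one protein sequence (1-based positions)."""

    sequence_id: str
    length: int
    cysteine_count: int
    cysteine_positions: tuple[int, ...]

    def __post_init__(self):
        if self.cysteine_count != len(self.cysteine_positions):
            raise ValueError("cysteine_count must equal number of positions")
        if any(p < 1 or p > self.length for p in self.cysteine_positions):
            raise ValueError("cysteine positions must lie within the sequence")
        if list(self.cysteine_positions) != sorted(set(self.cysteine_positions)):
            raise ValueError("cysteine positions must be strictly increasing")


def annotate_cysteines(source) -> list[SequenceAnnotation]:
    """Count and locate cysteines in each record of a protein FASTA.

    ``source`` is a path or open text handle.  Raises on an empty file and on
    records whose alphabet looks nucleotide rather than amino acid.
    """
    if isinstance(source, (str, Path)):
        handle = open(source)
        close = True
    else:
        handle, close = source, False
    try:
        annotations = []
        for record in SeqIO.parse(handle, "fasta"):
            seq = str(record.seq).upper()
            if not seq:
                raise ParseError(f"record {record.id!r} has an empty sequence")
            if set(seq) <= _NUCLEOTIDE:
                raise ParseError(
                    f"record {record.id!r} looks like a nucleotide sequence; "
                    "amino-acid FASTA expected"
                )
            positions = tuple(i + 1 for i, aa in enumerate(seq) if aa == "C")
            annotations.append(SequenceAnnotation(
                sequence_id=record.id, length=len(seq),
                cysteine_count=len(positions), cysteine_positions=positions))
    finally:
        if close:
            handle.close()
    if not annotations:
        raise ParseError("no FASTA records found")
    return annotations


def write_annotations(annotations: list[SequenceAnnotation], path) -> None:
    pd.DataFrame([{
        "sequence_id": a.sequence_id,
        "length": a.length,
        "cysteine_count": a.cysteine_count,
        "cysteine_positions": ";".join(map(str, a.cysteine_positions)),
    } for a in annotations]).to_csv(path, index=False)


def scatchard_report_row(label: str, fit) -> dict:
    """One Table-style report row for a Scatchard fit (units in column names)."""
    return {
        "adsorbent": label,
        "scatchard_equation": fit.equation,
        "K_A_e6_per_M": round(fit.ka_e6_per_M, 4),
        "K_A_sd_e6_per_M": round(fit.ka_sd, 4),
        "n_e7": round(fit.n_e7, 4),
        "n_sd_e7": round(fit.n_sd, 4),
        "R2": round(fit.r_squared, 6),
        "n_points": fit.n_points,
    }


def kinetics_report_row(label: str, fit) -> dict:
    return {
        "adsorbent": label,
        "model": fit.model,
        "equation": fit.equation,
        "k": round(fit.k, 6),
        "Q_e_ug_per_g": round(fit.q_e, 4),
        "R2": round(fit.r_squared, 6),
        "n_used": fit.n_used,
        "n_excluded": fit.n_excluded,
    }


def write_report(rows: list[dict], path) -> None:
    pd.DataFrame(rows).to_csv(path, index=False)


def fasta_text(records: dict[str, str]) -> str:
    """Render a dict of id → amino-acid sequence as FASTA text."""
    buf = _io.StringIO()
    for name, seq in records.items():
        buf.write(f">{name}\n")
        for i in range(0, len(seq), 60):
            buf.write(seq[i:i + 60] + "\n")
    return buf.getvalue()
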