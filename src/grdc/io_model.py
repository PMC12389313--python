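"""Domain types, drug-name normalization, and tabular readers/writers.

Every table the pipeline consumes is a delimited text file with a header:

* prescriptions  — ``SUBJECT_ID, HADM_ID, DRUG`` (one row per prescribed drug)
* risk table     — ``DRUG_A, DRUG_B, LEVEL`` (pairwise DDI severity labels)
* drug-gene map  — ``DRUG, GENE`` (one row per drug-target association)
* docking modes  — ``MODE, AFFINITY, RMSD`` (one ranked pose per row)

The canonical dialect is comma-separated UTF-8; every reader accepts an
explicit ``sep`` argument so tab-separated exports work unchanged.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "AdmissionDrugSet",
    "DockingMode",
    "DrugGeneMap",
    "RiskLevel",
    "RiskTable",
    "normalize_drug_name",
    "normalize_gene_symbol",
    "canonical_pair",
    "read_prescriptions",
    "write_prescriptions",
    "read_risk_table",
    "write_risk_table",
    "read_drug_gene_map",
    "write_drug_gene_map",
    "read_docking_modes",
    "write_docking_modes",
    "filter_prescriptions_by_diagnosis",
]

# ---------------------------------------------------------------------------
# drug-name normalization

_BRACKETS = re.compile(r"\([^()]*\)|\[[^\[\]]*\]|\{[^{}]*\}")
_DISALLOWED = re.compile(r"[^a-z0-9 \-]")
_WS = re.compile(r"\s+")


def normalize_drug_name(raw: str) -> str:
    """Normalize a free-text drug name to its canonical token.

    Applies, in order: lowercasing, removal of bracketed content
    (``()``, ``[]``, ``{}``, nested brackets stripped outside-in),
    deletion of every character outside ``[a-z0-9 -]``, whitespace
    collapse and trimming.  Idempotent.

    Raises
    ------
    ValueError
        If ``raw`` is empty, or nothing survives normalization.
    """
    if not isinstance(raw, str) or not raw.strip():
        raise ValueError(f"cannot normalize empty drug name: {raw!r}")
    name = raw.lower()
    # nested brackets: innermost pairs match first, repeat until stable
    while True:
        stripped = _BRACKETS.sub(" ", name)
        if stripped == name:
            break
        name = stripped
    name = _DISALLOWED.sub("", name)
    name = _WS.sub(" ", name).strip()
    if not name:
        raise ValueError(f"drug name empty after normalization: {raw!r}")
    return name


def normalize_gene_symbol(raw: str) -> str:
    """Upper-case and trim a gene symbol token."""
    sym = str(raw).strip().upper()
    if not sym:
        raise ValueError(f"empty gene symbol: {raw!r}")
    return sym


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Order-free key for an unordered drug pair."""
    return (a, b) if a <= b else (b, a)


# ---------------------------------------------------------------------------
# domain types


class RiskLevel(enum.Enum):
    """DDI severity label with a total order High > Moderate > Low > Unknown > None."""

    HIGH = "High"
    MODERATE = "Moderate"
    LOW = "Low"
    UNKNOWN = "Unknown"
    NONE = "None"

    @property
    def severity(self) -> int:
        return _SEVERITY[self]

    def __lt__(self, other: "RiskLevel") -> bool:
        if not isinstance(other, RiskLevel):
            return NotImplemented
        return self.severity < other.severity

    def __le__(self, other: "RiskLevel") -> bool:
        if not isinstance(other, RiskLevel):
            return NotImplemented
        return self.severity <= other.severity

    def __gt__(self, other: "RiskLevel") -> bool:
        if not isinstance(other, RiskLevel):
            return NotImplemented
        return self.severity > other.severity

    def __ge__(self, other: "RiskLevel") -> bool:
        if not isinstance(other, RiskLevel):
            return NotImplemented
        return self.severity >= other.severity

    @classmethod
    def from_token(cls, token: str) -> "RiskLevel":
        """Parse a severity token case-insensitively; single letters accepted."""
        t = str(token).strip().lower()
        try:
            return _TOKENS[t]
        except KeyError:
            raise ValueError(f"unrecognized risk level token: {token!r}") from None


_SEVERITY = {
    RiskLevel.HIGH: 4,
    RiskLevel.MODERATE: 3,
    RiskLevel.LOW: 2,
    RiskLevel.UNKNOWN: 1,
    RiskLevel.NONE: 0,
}

_TOKENS = {
    "high": RiskLevel.HIGH,
    "h": RiskLevel.HIGH,
    "moderate": RiskLevel.MODERATE,
    "m": RiskLevel.MODERATE,
    "low": RiskLevel.LOW,
    "l": RiskLevel.LOW,
    "unknown": RiskLevel.UNKNOWN,
    "u": RiskLevel.UNKNOWN,
    "none": RiskLevel.NONE,
    "n": RiskLevel.NONE,
}


@dataclass(frozen=True)
class AdmissionDrugSet:
    """The de-duplicated set of normalized drug names for one hospitalization.

    This is the mining unit: one admission contributes at most once to any
    combination's frequency count.
    """

    subject_id: str
    hadm_id: str
    drugs: frozenset[str]

    def __post_init__(self) -> None:
        if not self.drugs:
            raise ValueError(
                f"admission ({self.subject_id}, {self.hadm_id}) has no drugs"
            )


@dataclass(frozen=True)
class DockingMode:
    """One ranked docking pose: mode index, affinity (kcal/mol), RMSD (Å)."""

    mode_index: int
    affinity: float
    rmsd: float

    def __post_init__(self) -> None:
        if self.mode_index < 1:
            raise ValueError(f"mode_index must be positive, got {self.mode_index}")
        if self.rmsd < 0:
            raise ValueError(f"RMSD must be non-negative, got {self.rmsd}")


class RiskTable:
    """Symmetric lookup of pairwise DDI severity labels.

    An unordered drug pair maps to one :class:`RiskLevel`; a pair absent
    from the table is ``Unknown`` — the available data cannot assess it.
    """

    def __init__(self, pairs: Mapping[tuple[str, str], RiskLevel] | None = None):
        self._table: dict[tuple[str, str], RiskLevel] = {}
        if pairs:
            for (a, b), level in pairs.items():
                self.set(a, b, level)

    def set(self, a: str, b: str, level: RiskLevel) -> None:
        self._table[canonical_pair(a, b)] = level

    def get(self, a: str, b: str) -> RiskLevel:
        return self._table.get(canonical_pair(a, b), RiskLevel.UNKNOWN)

    def items(self) -> Iterable[tuple[tuple[str, str], RiskLevel]]:
        return self._table.items()

    def __len__(self) -> int:
        return len(self._table)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return canonical_pair(*pair) in self._table


class DrugGeneMap:
    """Mapping from normalized drug name to its set of target gene symbols.

    Unmapped drugs return the empty set.
    """

    def __init__(self, mapping: Mapping[str, Iterable[str]] | None = None):
        self._map: dict[str, frozenset[str]] = {}
        if mapping:
            for drug, genes in mapping.items():
                self._map[drug] = frozenset(normalize_gene_symbol(g) for g in genes)

    def genes(self, drug: str) -> frozenset[str]:
        return self._map.get(drug, frozenset())

    def drugs(self) -> list[str]:
        return sorted(self._map)

    def items(self) -> Iterable[tuple[str, frozenset[str]]]:
        return self._map.items()

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self._map.values():
            out |= genes
        return frozenset(out)

    def __len__(self) -> int:
        return len(self._map)


# ---------------------------------------------------------------------------
# readers / writers


def _read_table(path: str | Path, required: list[str], sep: str = ",") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    df.columns = [c.strip().upper() for c in df.columns]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return df


def read_prescriptions(path: str | Path, sep: str = ",") -> list[AdmissionDrugSet]:
    """Read a prescriptions table into per-admission drug sets.

    One :class:`AdmissionDrugSet` is produced per distinct
    ``(SUBJECT_ID, HADM_ID)``; drug names are normalized and de-duplicated
    within the admission. Rows whose drug name normalizes to nothing are
    rejected.
    """
    df = _read_table(path, ["SUBJECT_ID", "HADM_ID", "DRUG"], sep=sep)
    if df.empty:
        return []
    df = df.assign(DRUG=df["DRUG"].map(normalize_drug_name))
    out: list[AdmissionDrugSet] = []
    for (subj, hadm), grp in df.groupby(["SUBJECT_ID", "HADM_ID"], sort=True):
        out.append(
            AdmissionDrugSet(
                subject_id=str(subj), hadm_id=str(hadm), drugs=frozenset(grp["DRUG"])
            )
        )
    return out


def write_prescriptions(
    admissions: Iterable[AdmissionDrugSet], path: str | Path, sep: str = ","
) -> None:
    """Write admissions in the canonical dialect (sorted, one row per drug)."""
    rows = [
        {"SUBJECT_ID": a.subject_id, "HADM_ID": a.hadm_id, "DRUG": d}
        for a in sorted(admissions, key=lambda a: (a.subject_id, a.hadm_id))
        for d in sorted(a.drugs)
    ]
    pd.DataFrame(rows, columns=["SUBJECT_ID", "HADM_ID", "DRUG"]).to_csv(
        path, sep=sep, index=False
    )


def read_risk_table(path: str | Path, sep: str = ",") -> RiskTable:
    """Read a pairwise severity table; lookup is symmetric, names normalized."""
    df = _read_table(path, ["DRUG_A", "DRUG_B", "LEVEL"], sep=sep)
    table = RiskTable()
    for i, row in df.iterrows():
        try:
            level = RiskLevel.from_token(row["LEVEL"])
        except ValueError as exc:
            raise ValueError(f"{path} row {i}: {exc}") from None
        table.set(
            normalize_drug_name(row["DRUG_A"]),
            normalize_drug_name(row["DRUG_B"]),
            level,
        )
    return table


def write_risk_table(table: RiskTable, path: str | Path, sep: str = ",") -> None:
    rows = [
        {"DRUG_A": a, "DRUG_B": b, "LEVEL": level.value}
        for (a, b), level in sorted(table.items())
    ]
    pd.DataFrame(rows, columns=["DRUG_A", "DRUG_B", "LEVEL"]).to_csv(
        path, sep=sep, index=False
    )


def read_drug_gene_map(path: str | Path, sep: str = ",") -> DrugGeneMap:
    """Read drug→gene rows and aggregate gene sets per normalized drug."""
    df = _read_table(path, ["DRUG", "GENE"], sep=sep)
    agg: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        drug = normalize_drug_name(row["DRUG"])
        agg.setdefault(drug, set()).add(normalize_gene_symbol(row["GENE"]))
    return DrugGeneMap(agg)


def write_drug_gene_map(genes: DrugGeneMap, path: str | Path, sep: str = ",") -> None:
    rows = [
        {"DRUG": drug, "GENE": gene}
        for drug, gene_set in sorted(genes.items())
        for gene in sorted(gene_set)
    ]
    pd.DataFrame(rows, columns=["DRUG", "GENE"]).to_csv(path, sep=sep, index=False)


def read_docking_modes(path: str | Path, sep: str = ",") -> list[DockingMode]:
    """Read one docking run; modes are returned sorted by index, mode 1 first.

    Rejects duplicate mode indices, negative RMSD, and runs without the
    reference mode 1.
    """
    df = _read_table(path, ["MODE", "AFFINITY", "RMSD"], sep=sep)
    modes = [
        DockingMode(
            mode_index=int(row["MODE"]),
            affinity=float(row["AFFINITY"]),
            rmsd=float(row["RMSD"]),
        )
        for _, row in df.iterrows()
    ]
    indices = [m.mode_index for m in modes]
    dupes = {i for i in indices if indices.count(i) > 1}
    if dupes:
        raise ValueError(f"{path}: duplicate mode index(es) {sorted(dupes)}")
    if 1 not in indices:
        raise ValueError(f"{path}: docking run lacks the reference mode 1")
    return sorted(modes, key=lambda m: m.mode_index)


def write_docking_modes(
    modes: Iterable[DockingMode], path: str | Path, sep: str = ","
) -> None:
    rows = [
        {"MODE": m.mode_index, "AFFINITY": m.affinity, "RMSD": m.rmsd}
        for m in sorted(modes, key=lambda m: m.mode_index)
    ]
    pd.DataFrame(rows, columns=["MODE", "AFFINITY", "RMSD"]).to_csv(
        path, sep=sep, index=False
    )


def filter_prescriptions_by_diagnosis(
    prescriptions_path: str | Path,
    diagnoses_path: str | Path,
    icd9_codes: Iterable[str] = ("7100", "28981"),
    sep: str = ",",
) -> list[AdmissionDrugSet]:
    """Keep only admissions of subjects carrying one of the given ICD-9 codes.

    Plumbing for cohort construction from a DIAGNOSES-style table with
    columns ``SUBJECT_ID, ICD9_CODE``; identifiers are opaque strings.
    """
    diag = _read_table(diagnoses_path, ["SUBJECT_ID", "ICD9_CODE"], sep=sep)
    codes = {str(c).strip() for c in icd9_codes}
    keep = {
        str(s)
        for s, c in zip(diag["SUBJECT_ID"], diag["ICD9_CODE"])
        if str(c).strip() in codes
    }
    return [a for a in read_prescriptions(prescriptions_path, sep=sep) if a.subject_id in keep]
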