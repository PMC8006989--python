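"""Input handling: FASTA sequences, class manifests, amino-acid property
tables, and the deposited MAT-format PDB-ID lists.

Protein sequences are restricted to the 20 canonical amino acids; records
containing any other letter, or shorter than 20 residues, are dropped with a
logged reason — the downstream feature definitions exist only on the
canonical alphabet and need at least 20 residues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("featnet")

#: The 20 canonical amino acids, in the conventional one-letter order.
AMINO_ACIDS: str = "ARNDCQEGHILKMFPSTWYV"
_AA_SET = frozenset(AMINO_ACIDS)

#: Minimum accepted sequence length.
MIN_LENGTH: int = 20


class EmptyInputError(ValueError):
    """No records survived filtering."""


class ManifestError(ValueError):
    """Class manifest violates its invariants."""


class PropertyTableError(ValueError):
    """Amino-acid property table is malformed."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: an identifier and a canonical amino-acid sequence."""

    id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class FilterReport:
    """Bookkeeping for records dropped while reading a FASTA file."""

    total: int = 0
    kept: int = 0
    dropped_non_canonical: int = 0
    dropped_short: int = 0

    @property
    def dropped(self) -> int:
        return self.dropped_non_canonical + self.dropped_short


def read_fasta(path: str | Path) -> tuple[list[ProteinRecord], FilterReport]:
    """Read protein records from a FASTA file.

    Sequences are upper-cased. Records with non-canonical letters or fewer
    than 20 residues are excluded and counted in the returned report.

    Raises
    ------
    OSError
        If the file cannot be read.
    EmptyInputError
        If no record survives filtering.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    report = FilterReport()
    for entry in SeqIO.parse(str(path), "fasta"):
        report.total += 1
        seq = str(entry.seq).upper()
        if not set(seq) <= _AA_SET:
            report.dropped_non_canonical += 1
            logger.warning("dropping %s: non-canonical letters %s",
                           entry.id, sorted(set(seq) - _AA_SET))
            continue
        if len(seq) < MIN_LENGTH:
            report.dropped_short += 1
            logger.warning("dropping %s: length %d < %d", entry.id, len(seq), MIN_LENGTH)
            continue
        records.append(ProteinRecord(id=entry.id, sequence=seq))
    report.kept = len(records)
    if not records:
        raise EmptyInputError(f"no valid protein records in {path}")
    return records, report


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records to FASTA (60-column wrap, deterministic byte output)."""
    seq_records = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        SeqIO.write(seq_records, fh, "fasta")


@dataclass
class ClassManifest:
    """Mapping from protein id to structural-class label.

    Every id appears once and every class has at least two members (a class
    of one protein cannot support cross-protein feature statistics).
    """

    mapping: dict[str, str]
    class_labels: list[str] = field(init=False)

    def __post_init__(self) -> None:
        counts: dict[str, int] = {}
        for label in self.mapping.values():
            counts[label] = counts.get(label, 0) + 1
        for label, n in counts.items():
            if n < 2:
                raise ManifestError(f"class {label!r} has {n} member(s); need >= 2")
        # stable order of first appearance
        self.class_labels = list(dict.fromkeys(self.mapping.values()))

    def ids_for(self, label: str) -> list[str]:
        """Protein ids of one class, in manifest order."""
        return [pid for pid, lab in self.mapping.items() if lab == label]

    def __len__(self) -> int:
        return len(self.mapping)


def read_class_manifest(path: str | Path) -> ClassManifest:
    """Read a two-column ``id<TAB>class`` manifest.

    Raises :class:`ManifestError` on duplicate ids or singleton classes.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "class"],
                     dtype=str, comment="#")
    if df["id"].duplicated().any():
        dups = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ManifestError(f"duplicate protein ids in manifest: {dups}")
    return ClassManifest(dict(zip(df["id"], df["class"])))


def write_class_manifest(manifest: ClassManifest, path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid, label in manifest.mapping.items():
            fh.write(f"{pid}\t{label}\n")


# ---------------------------------------------------------------------------
# amino-acid property tables
# ---------------------------------------------------------------------------

@dataclass
class AAPropertyTable:
    """The amino-acid property tables every feature scheme needs.

    ``factors`` is the 20 x 10 table of physical property factors used by the
    averaged-property-factor features. ``pseaac_triplet`` is the 20 x 3 table
    of standardized hydrophobicity, hydrophilicity and side-chain mass used by
    the PseAAC correlation function; each column has mean 0 and sample SD 1
    across the 20 amino acids.
    """

    factors: pd.DataFrame
    pseaac_triplet: pd.DataFrame

    def __post_init__(self) -> None:
        for name, df, ncol in (("factors", self.factors, 10),
                               ("pseaac_triplet", self.pseaac_triplet, 3)):
            if df.shape != (20, ncol):
                raise PropertyTableError(
                    f"{name} table has shape {df.shape}, expected (20, {ncol})")
            if df.isna().any().any():
                raise PropertyTableError(f"{name} table contains missing values")
            unknown = set(df.index) - _AA_SET
            if unknown:
                raise PropertyTableError(f"{name} table has unknown rows {unknown}")
            if len(set(df.index)) != 20:
                raise PropertyTableError(f"{name} table rows are not the 20 amino acids")


def _read_aa_table(source: str | Path, bundled: str | None) -> pd.DataFrame:
    if bundled is not None and str(source) == bundled:
        ref = resources.files("featnet.data") / f"{bundled}.tsv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", comment="#", index_col="aa")
    else:
        df = pd.read_csv(source, sep="\t", comment="#", index_col="aa")
    return df.astype(float)


def _standardize(df: pd.DataFrame) -> pd.DataFrame:
    return (df - df.mean()) / df.std(ddof=1)


def load_property_table(factors_source: str | Path = "kidera_factors",
                        triplet_source: str | Path = "pseaac_properties",
                        ) -> AAPropertyTable:
    """Load (bundled or user-supplied) amino-acid property tables.

    The triplet columns are standardized to mean 0 / sample SD 1 over the 20
    amino acids at load time; the ten factors are used as shipped (they are
    published already normalized). Rows are reindexed to the canonical
    one-letter order.
    """
    factors = _read_aa_table(factors_source, "kidera_factors")
    triplet = _read_aa_table(triplet_source, "pseaac_properties")
    table = AAPropertyTable(factors=factors, pseaac_triplet=triplet)  # shape checks
    factors = table.factors.reindex(list(AMINO_ACIDS))
    triplet = _standardize(table.pseaac_triplet.reindex(list(AMINO_ACIDS)))
    return AAPropertyTable(factors=factors, pseaac_triplet=triplet)


# ---------------------------------------------------------------------------
# deposited PDB-ID lists (MAT containers)
# ---------------------------------------------------------------------------

#: Variable names used by the deposited ID lists, with the class each encodes.
MAT_VARIABLE_CLASSES: Mapping[str, str] = {
    "PID_A": "mainly_alpha", "PID_B": "mainly_beta", "PID_M": "mixed",
    "PID_1": "all_alpha", "PID_2": "all_beta", "PID_3": "a/b", "PID_4": "a+b",
}


def _as_string_list(var: np.ndarray) -> list[str]:
    """Flatten a MAT string container (cell array or char matrix) to a list."""
    arr = np.asarray(var)
    if arr.dtype == object:
        return [str(np.asarray(x).item()).strip() for x in arr.ravel()]
    if arr.dtype.kind in "US":
        if arr.ndim <= 1:
            return [str(x).strip() for x in np.atleast_1d(arr)]
        return ["".join(str(c) for c in row).strip() for row in arr]
    raise ValueError(f"cannot interpret MAT variable of dtype {arr.dtype} as strings")


def load_pdb_id_lists(path: str | Path) -> dict[str, list[str]]:
    """Read per-class PDB-ID lists from a deposited MAT container.

    Recognizes the variables ``PID_A``/``PID_B``/``PID_M`` (three-class) or
    ``PID_1``..``PID_4`` (four-class). No sequence retrieval is performed.

    Raises
    ------
    ValueError
        If the file holds none of the expected variable names.
    """
    from scipy.io import loadmat

    mat = loadmat(str(path))
    out: dict[str, list[str]] = {}
    for var, label in MAT_VARIABLE_CLASSES.items():
        if var in mat:
            out[label] = _as_string_list(mat[var])
    if not out:
        raise ValueError(
            f"{path} holds no PID_* variables "
            f"(expected some of {sorted(MAT_VARIABLE_CLASSES)})")
    logger.info("loaded %d PDB ids in %d classes from %s",
                sum(len(v) for v in out.values()), len(out), path)
    return out
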