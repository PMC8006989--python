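"""Protein sequence feature extraction.

Six feature schemes are produced per protein:

* the natural vector's three 20-component blocks — per amino acid its count
  (``N``), mean position (``mu``), and second normalized central moment
  (``D``);
* the ten averaged property factors (``APF``) — sequence means of ten
  physical property factors;
* pseudo amino-acid composition at ``lambda = 0`` (plain frequencies,
  ``PseAAC0``) and ``lambda = 10`` (frequencies plus ten sequence-order
  correlation tiers, ``PseAAC10``).

Per structural class and scheme, the feature vectors of the class members are
stacked into an ``N_s x K`` feature matrix whose columns are the feature
series analyzed downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .sequence_io import (AMINO_ACIDS, AAPropertyTable, ClassManifest,
                          ProteinRecord, load_property_table)

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: The six feature schemes and their dimensionalities.
SCHEMES: dict[str, int] = {
    "N": 20, "mu": 20, "D": 20, "APF": 10, "PseAAC0": 20, "PseAAC10": 30,
}


@dataclass(frozen=True)
class NaturalVectorParams:
    """``position_offset`` is the distance assigned to the first residue:
    1 (default; position index) or 0 (origin at the first residue)."""

    position_offset: int = 1

    def __post_init__(self) -> None:
        if self.position_offset not in (0, 1):
            raise ValueError("position_offset must be 0 or 1")


@dataclass(frozen=True)
class PseAACParams:
    """PseAAC settings: tier count ``lam`` (lambda), sequence-order weight
    ``w`` (default 0.05), and the standardized property triplet."""

    lam: int = 10
    w: float = 0.05
    triplet: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")
        if self.w <= 0:
            raise ValueError("weight w must be positive")


def _encode(sequence: str) -> np.ndarray:
    try:
        return np.fromiter((_AA_INDEX[c] for c in sequence), dtype=np.intp,
                           count=len(sequence))
    except KeyError as exc:  # pragma: no cover - guarded upstream
        raise ValueError(f"non-canonical residue {exc}") from exc


def natural_vector(record: ProteinRecord,
                   params: NaturalVectorParams = NaturalVectorParams(),
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Compute the natural-vector blocks ``(n, mu, d2)``, each of length 20.

    For amino acid ``k`` with occurrence positions ``s[k][i]`` (the first
    residue sits at ``position_offset``): ``n_k`` is the count,
    ``mu_k = (1/n_k) sum_i s[k][i]``, and
    ``d2_k = sum_i (s[k][i] - mu_k)^2 / (n_k * n)`` with ``n`` the sequence
    length. Absent amino acids contribute ``(0, 0, 0)``.
    """
    if not record.sequence:
        raise ValueError("empty sequence")
    codes = _encode(record.sequence)
    n = len(codes)
    positions = np.arange(n, dtype=float) + params.position_offset
    counts = np.bincount(codes, minlength=20).astype(float)
    totals = np.bincount(codes, weights=positions, minlength=20)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu = np.where(counts > 0, totals / counts, 0.0)
    dev2 = (positions - mu[codes]) ** 2
    ss = np.bincount(codes, weights=dev2, minlength=20)
    with np.errstate(divide="ignore", invalid="ignore"):
        d2 = np.where(counts > 0, ss / (counts * n), 0.0)
    return counts, mu, d2


def apf_vector(record: ProteinRecord, table: AAPropertyTable) -> np.ndarray:
    """Averaged property factors: component ``m`` is the sequence mean of the
    ``m``-th property factor over the residues."""
    codes = _encode(record.sequence)
    factors = table.factors.to_numpy()  # rows in canonical AA order
    return factors[codes].mean(axis=0)


def pseaac_vector(record: ProteinRecord, params: PseAACParams) -> np.ndarray:
    """Type-1 pseudo amino-acid composition, a ``20 + lambda`` vector.

    The correlation function ``Theta(a, b)`` is the mean of the squared
    differences of the three standardized properties of residues ``a`` and
    ``b``; the ``j``-th tier is the average of ``Theta`` over all residue
    pairs ``j`` apart. The 20 frequencies and the ``lambda`` weighted tiers
    share the denominator ``sum(f) + w * sum(theta)``, so the output sums
    to 1 for every ``lambda``.
    """
    n = len(record.sequence)
    if params.lam >= n:
        raise ValueError(f"lambda={params.lam} must be < sequence length {n}")
    triplet = params.triplet
    if triplet is None:
        triplet = load_property_table().pseaac_triplet
    codes = _encode(record.sequence)
    freq = np.bincount(codes, minlength=20) / n
    if params.lam == 0:
        # the shared denominator is exactly sum(f) = 1: plain frequencies
        return freq

    props = triplet.to_numpy()[codes]  # n x 3
    theta = np.empty(params.lam)
    for j in range(1, params.lam + 1):
        diff = props[j:] - props[:-j]
        theta[j - 1] = np.mean(diff ** 2)  # mean over pairs and properties

    denom = freq.sum() + params.w * theta.sum()
    return np.concatenate([freq, params.w * theta]) / denom


@dataclass
class FeatureMatrix:
    """``N_s x K`` feature matrix for one structural class and one scheme.

    Columns are the feature series ``X_1..X_K``; rows align with
    ``protein_ids``.
    """

    values: np.ndarray
    scheme: str
    feature_labels: list[str]
    protein_ids: list[str]
    class_label: str
    ground_truth: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        ns, k = self.values.shape
        if len(self.feature_labels) != k or len(self.protein_ids) != ns:
            raise ValueError("labels do not match matrix shape")
        if self.scheme in SCHEMES and SCHEMES[self.scheme] != k:
            raise ValueError(
                f"scheme {self.scheme} expects K={SCHEMES[self.scheme]}, got {k}")

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def permuted(self, order: np.ndarray) -> "FeatureMatrix":
        """Jointly permute the rows (proteins) by ``order``."""
        return FeatureMatrix(self.values[order], self.scheme,
                             self.feature_labels,
                             [self.protein_ids[i] for i in order],
                             self.class_label, self.ground_truth)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.protein_ids, name="id"),
                            columns=self.feature_labels)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path, scheme: str, class_label: str,
                 ) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(), scheme, list(df.columns),
                   [str(i) for i in df.index], class_label)


def feature_labels(scheme: str) -> list[str]:
    """Column labels for one scheme (amino-acid letters, property indices,
    or letters plus correlation tiers)."""
    aas = list(AMINO_ACIDS)
    if scheme in ("N", "mu", "D", "PseAAC0"):
        return aas
    if scheme == "APF":
        return [f"P{m}" for m in range(1, 11)]
    if scheme == "PseAAC10":
        return aas + [f"tier-{j}" for j in range(1, 11)]
    raise ValueError(f"unknown scheme {scheme!r}")


def feature_vector(record: ProteinRecord, scheme: str,
                   table: AAPropertyTable,
                   nv_params: NaturalVectorParams,
                   pseaac_w: float) -> np.ndarray:
    """One protein's feature vector under one scheme."""
    if scheme in ("N", "mu", "D"):
        n, mu, d2 = natural_vector(record, nv_params)
        return {"N": n, "mu": mu, "D": d2}[scheme]
    if scheme == "APF":
        return apf_vector(record, table)
    if scheme in ("PseAAC0", "PseAAC10"):
        lam = 0 if scheme == "PseAAC0" else 10
        return pseaac_vector(record, PseAACParams(lam=lam, w=pseaac_w,
                                                  triplet=table.pseaac_triplet))
    raise ValueError(f"unknown scheme {scheme!r}")


def build_feature_matrices(records: list[ProteinRecord],
                           manifest: ClassManifest,
                           schemes: list[str] | None = None,
                           table: AAPropertyTable | None = None,
                           nv_params: NaturalVectorParams = NaturalVectorParams(),
                           pseaac_w: float = 0.05,
                           ) -> list[FeatureMatrix]:
    """Assemble one feature matrix per (class, scheme).

    Rows follow manifest order within each class. Every record id must be
    present in the manifest.
    """
    schemes = list(SCHEMES) if schemes is None else list(schemes)
    for s in schemes:
        if s not in SCHEMES:
            raise ValueError(f"unknown scheme {s!r}")
    if table is None:
        table = load_property_table()
    by_id = {r.id: r for r in records}
    missing = [r.id for r in records if r.id not in manifest.mapping]
    if missing:
        raise KeyError(f"record ids missing from manifest: {missing[:5]}")

    out: list[FeatureMatrix] = []
    for label in manifest.class_labels:
        ids = [pid for pid in manifest.ids_for(label) if pid in by_id]
        for scheme in schemes:
            rows = [feature_vector(by_id[pid], scheme, table, nv_params, pseaac_w)
                    for pid in ids]
            out.append(FeatureMatrix(np.vstack(rows), scheme,
                                     feature_labels(scheme), ids, label))
    return out
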