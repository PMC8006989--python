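"""Synthetic test inputs: class-structured protein sequences and feature
matrices with planted statistical structure.

Sequence simulation plants structure at the composition level: each class
has its own amino-acid profile (optionally Dirichlet-perturbed from a shared
base), so cross-protein feature statistics differ between classes the way
real structural classes differ in residue usage. An optional first-order
Markov repeat bias induces arrangement structure. Realistic protein
evolution is out of scope — the generator exists to exercise every pipeline
stage without any download.

Feature-series simulation provides ground truth for the connectivity
measures: independent columns, a planted correlation matrix, a nonlinear
(squared-latent) pair, or directed autoregressive (VAR) coupling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .feature_extraction import FeatureMatrix
from .sequence_io import (AMINO_ACIDS, ClassManifest, ProteinRecord,
                          write_class_manifest, write_fasta)


@dataclass
class ClassSpec:
    """One simulated structural class.

    ``composition`` is a point on the 20-simplex (probabilities in canonical
    amino-acid order). Lengths are ``length_min`` plus a negative-binomial
    excess with the given mean and dispersion (NB size parameter; larger =
    closer to Poisson). ``markov_coupling`` in [0, 1) is the probability that
    a residue repeats its predecessor, planting first-order arrangement
    structure; 0 means i.i.d. draws.
    """

    label: str
    composition: np.ndarray
    n_proteins: int
    length_min: int = 20
    length_mean: float = 120.0
    length_dispersion: float = 5.0
    markov_coupling: float = 0.0

    def __post_init__(self) -> None:
        self.composition = np.asarray(self.composition, dtype=float)
        if self.composition.shape != (20,) or (self.composition < 0).any() \
                or abs(self.composition.sum() - 1) > 1e-9:
            raise ValueError(f"class {self.label!r}: composition must be a "
                             "20-simplex vector")
        if self.length_min < 20:
            raise ValueError("length_min must be >= 20")
        if not 0 <= self.markov_coupling < 1:
            raise ValueError("markov_coupling must be in [0, 1)")


@dataclass
class SequenceSimSpec:
    classes: list[ClassSpec]
    seed: int = 0


def default_sequence_spec(n_classes: int = 3, n_proteins: int = 100,
                          seed: int = 0, concentration: float = 50.0,
                          ) -> SequenceSimSpec:
    """Class profiles Dirichlet-perturbed around a shared uniform base.

    ``concentration`` controls how far class compositions sit from uniform
    (larger = closer); 50 gives the mild between-class composition shifts
    that drive distinguishable cross-protein feature statistics.
    """
    rng = np.random.default_rng(seed)
    classes = [
        ClassSpec(label=f"class_{c + 1}",
                  composition=rng.dirichlet(np.full(20, concentration)),
                  n_proteins=n_proteins)
        for c in range(n_classes)
    ]
    return SequenceSimSpec(classes=classes, seed=seed)


def _draw_sequence(rng: np.random.Generator, length: int,
                   composition: np.ndarray, coupling: float) -> str:
    codes = rng.choice(20, size=length, p=composition)
    if coupling > 0:
        repeat = rng.random(length) < coupling
        for i in range(1, length):
            if repeat[i]:
                codes[i] = codes[i - 1]
    return "".join(AMINO_ACIDS[c] for c in codes)


def simulate_sequences(spec: SequenceSimSpec,
                       fasta_path: str | Path | None = None,
                       manifest_path: str | Path | None = None,
                       ) -> tuple[list[ProteinRecord], ClassManifest]:
    """Draw per-class protein sequences; deterministic given the seed.

    Optionally writes the FASTA and manifest files (byte-identical across
    runs with the same spec).
    """
    rng = np.random.default_rng(spec.seed)
    records: list[ProteinRecord] = []
    mapping: dict[str, str] = {}
    for cls in spec.classes:
        mean_excess = max(cls.length_mean - cls.length_min, 1e-9)
        r = cls.length_dispersion
        p = r / (r + mean_excess)
        lengths = cls.length_min + rng.negative_binomial(r, p, cls.n_proteins)
        for i, length in enumerate(lengths):
            pid = f"{cls.label}_p{i + 1:04d}"
            seq = _draw_sequence(rng, int(length), cls.composition,
                                 cls.markov_coupling)
            records.append(ProteinRecord(pid, seq))
            mapping[pid] = cls.label
    manifest = ClassManifest(mapping)
    if fasta_path is not None:
        write_fasta(records, fasta_path)
    if manifest_path is not None:
        write_class_manifest(manifest, manifest_path)
    return records, manifest


# ---------------------------------------------------------------------------
# feature-series simulation
# ---------------------------------------------------------------------------

@dataclass
class SeriesSimSpec:
    """Planted dependence structure for simulated feature series.

    structure
        ``independent`` — K i.i.d. standard-normal columns;
        ``correlated`` — multivariate normal with correlation matrix ``rho``
        (must be positive semi-definite);
        ``nonlinear`` — column 1 is the standardized square of column 0
        (strong dependence invisible to linear correlation), remaining
        columns independent;
        ``var_coupled`` — first-order vector autoregression with directed
        ``edges`` [(source, target, coefficient), ...] and innovation SD
        ``noise_sd`` (coefficient matrix must have spectral radius < 1).
    """

    n: int
    structure: str = "independent"
    n_features: int = 4
    rho: np.ndarray | None = None
    edges: list[tuple[int, int, float]] = field(default_factory=list)
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.structure not in ("independent", "correlated", "nonlinear",
                                  "var_coupled"):
            raise ValueError(f"unknown structure {self.structure!r}")


def simulate_feature_series(spec: SeriesSimSpec) -> FeatureMatrix:
    """Generate an ``n x K`` feature matrix realizing the requested
    dependence, with the planted ground truth attached."""
    rng = np.random.default_rng(spec.seed)
    k = spec.n_features
    truth: dict = {"structure": spec.structure, "seed": spec.seed}

    if spec.structure == "independent":
        x = rng.standard_normal((spec.n, k))
    elif spec.structure == "correlated":
        rho = np.asarray(spec.rho, dtype=float)
        if rho.shape != (k, k):
            raise ValueError("rho must be K x K")
        eigvals = np.linalg.eigvalsh(rho)
        if eigvals.min() < -1e-10:
            raise ValueError("rho is not positive semi-definite")
        x = rng.multivariate_normal(np.zeros(k), rho, size=spec.n,
                                    method="eigh")
        truth["rho"] = rho.tolist()
    elif spec.structure == "nonlinear":
        x = rng.standard_normal((spec.n, k))
        z = x[:, 0] ** 2
        x[:, 1] = (z - z.mean()) / z.std()
        truth["nonlinear_pair"] = [0, 1]
    else:  # var_coupled
        c = np.zeros((k, k))
        for src, dst, coef in spec.edges:
            c[dst, src] = coef
        radius = np.abs(np.linalg.eigvals(c)).max()
        if radius >= 1:
            raise ValueError(f"VAR spectral radius {radius:.3f} >= 1")
        burn = 100
        x = np.zeros((spec.n + burn, k))
        noise = rng.normal(0, spec.noise_sd, (spec.n + burn, k))
        for t in range(1, spec.n + burn):
            x[t] = c @ x[t - 1] + noise[t]
        x = x[burn:]
        truth["edges"] = [list(e) for e in spec.edges]
        truth["noise_sd"] = spec.noise_sd

    labels = [f"X{j + 1}" for j in range(k)]
    ids = [f"s{i + 1}" for i in range(spec.n)]
    return FeatureMatrix(x, scheme=f"sim_{spec.structure}",
                         feature_labels=labels, protein_ids=ids,
                         class_label="synthetic", ground_truth=truth)


def write_ground_truth(fm: FeatureMatrix, path: str | Path) -> None:
    """Sidecar JSON carrying the planted structure, so tests read rather
    than re-derive it."""
    with open(path, "w") as fh:
        json.dump(fm.ground_truth or {}, fh, indent=2)
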