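"""SNP quality control and pedigree/genomic/single-step relationship matrices.

The single-step evaluation needs the inverse of the combined relationship
matrix H, which augments the pedigree numerator relationship matrix A with
a genomic matrix G on the genotyped subset:

    H^-1 = A^-1 + [[0, 0], [0, G^-1 - A22^-1]]

with tau = omega = 1 (no scaling). G follows VanRaden's first method with
observed allele frequencies, optionally tuned so its mean diagonal and mean
off-diagonal match the pedigree-based A22, and blended with A22 to keep it
invertible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeMatrix",
    "QCReport",
    "RelationshipSet",
    "snp_qc",
    "pedigree_A",
    "genomic_G",
    "h_inverse",
    "build_relationships",
    "write_matrix_coo",
    "read_matrix_coo",
    "read_genotype_tsv",
    "write_genotype_tsv",
]

MISSING = -1  # missing genotype call code


@dataclass
class GenotypeMatrix:
    """Animals x SNPs genotype calls in {0, 1, 2}, ``MISSING`` (-1) if absent."""

    animal_ids: np.ndarray
    snp_ids: np.ndarray
    calls: np.ndarray  # int8, shape (n_animals, n_snps)

    def __post_init__(self):
        self.animal_ids = np.asarray(self.animal_ids)
        self.snp_ids = np.asarray(self.snp_ids)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.animal_ids), len(self.snp_ids)):
            raise ValueError("calls shape inconsistent with animal/SNP ids")
        bad = ~np.isin(self.calls, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("genotype calls must be 0, 1, 2 or missing (-1)")

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def allele_freqs(self) -> np.ndarray:
        """Per-SNP frequency of the counted allele among non-missing calls."""
        obs = self.calls != MISSING
        n = obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(obs, self.calls, 0).sum(axis=0) / np.maximum(2 * n, 1)


@dataclass
class QCReport:
    n_snps_in: int
    n_removed_callrate: int
    n_removed_maf: int
    n_removed_hwe: int
    n_snps_out: int
    n_animals_out: int

    def __post_init__(self):
        removed = self.n_removed_callrate + self.n_removed_maf + self.n_removed_hwe
        if self.n_snps_out != self.n_snps_in - removed:
            raise ValueError("QC tallies do not add up")


@dataclass
class RelationshipSet:
    """Pedigree A, genomic G and the combined H^-1 over one animal ordering."""

    animal_ids: np.ndarray
    A: np.ndarray
    genotyped_index: np.ndarray  # positions of genotyped animals in animal_ids
    A22: Optional[np.ndarray] = None
    G: Optional[np.ndarray] = None
    H_inv: np.ndarray = field(default=None)  # type: ignore[assignment]
    _H: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def H(self) -> np.ndarray:
        """Dense H, materialized lazily by inverting H^-1 (equals A without genomics)."""
        if self._H is None:
            if len(self.genotyped_index) == 0:
                self._H = self.A
            else:
                self._H = np.linalg.inv(self.H_inv)
        return self._H


def snp_qc(
    genotypes: GenotypeMatrix,
    call_rate_min: float = 0.90,
    maf_min: float = 0.05,
    hwe_alpha: float = 0.05,
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove SNPs by call rate, then minor allele frequency, then a 1-df
    chi-square Hardy-Weinberg goodness-of-fit test; each SNP is attributed to
    the first rule it fails, in that order."""
    if genotypes.n_snps == 0 or genotypes.n_animals == 0:
        raise ValueError("need at least one SNP and one animal")
    calls = genotypes.calls
    obs = calls != MISSING
    n_called = obs.sum(axis=0)
    call_rate = n_called / genotypes.n_animals
    fail_cr = call_rate < call_rate_min

    freq = genotypes.allele_freqs()
    maf = np.minimum(freq, 1.0 - freq)
    fail_maf = (maf < maf_min) & ~fail_cr

    # HWE chi-square with 1 df from genotype counts among called animals
    n0 = ((calls == 0) & obs).sum(axis=0)
    n1 = ((calls == 1) & obs).sum(axis=0)
    n2 = ((calls == 2) & obs).sum(axis=0)
    n = np.maximum(n_called, 1)
    p = (2 * n2 + n1) / (2 * n)
    q = 1.0 - p
    exp = np.stack([q**2 * n, 2 * p * q * n, p**2 * n])
    obs_counts = np.stack([n0, n1, n2])
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(exp > 0, (obs_counts - exp) ** 2 / np.where(exp > 0, exp, 1), 0.0).sum(axis=0)
    hwe_p = stats.chi2.sf(chi2, df=1)
    fail_hwe = (hwe_p < hwe_alpha) & ~fail_cr & ~fail_maf

    keep = ~(fail_cr | fail_maf | fail_hwe)
    if not keep.any():
        raise ValueError("quality control removed every SNP")
    out = GenotypeMatrix(
        animal_ids=genotypes.animal_ids,
        snp_ids=genotypes.snp_ids[keep],
        calls=calls[:, keep],
    )
    report = QCReport(
        n_snps_in=genotypes.n_snps,
        n_removed_callrate=int(fail_cr.sum()),
        n_removed_maf=int(fail_maf.sum()),
        n_removed_hwe=int(fail_hwe.sum()),
        n_snps_out=int(keep.sum()),
        n_animals_out=genotypes.n_animals,
    )
    return out, report


def _pedigree_indices(pedigree: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return animal ids and 0-based sire/dam indices (-1 for unknown),
    checking that parents precede offspring."""
    ids = pedigree["animal_id"].to_numpy()
    if len(np.unique(ids)) != len(ids):
        raise ValueError("duplicate animal ids in pedigree")
    pos = {a: i for i, a in enumerate(ids)}

    def parent_idx(col):
        out = np.full(len(ids), -1, dtype=np.int64)
        for i, pid in enumerate(pedigree[col].to_numpy()):
            if pid in (0, "0", None) or (isinstance(pid, float) and np.isnan(pid)):
                continue
            if pid not in pos:
                raise ValueError(f"parent {pid!r} never appears as an animal")
            j = pos[pid]
            if j >= i:
                raise ValueError("pedigree not sorted: parent after offspring (cycle?)")
            out[i] = j
        return out

    return ids, parent_idx("sire_id"), parent_idx("dam_id")


def pedigree_A(pedigree: pd.DataFrame) -> np.ndarray:
    """Numerator relationship matrix by the tabular method, with inbreeding.

    ``pedigree`` needs columns animal_id, sire_id, dam_id with 0/NaN for
    unknown parents and parents stored before their offspring.
    """
    ids, sire, dam = _pedigree_indices(pedigree)
    n = len(ids)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        if s >= 0 and d >= 0:
            A[i, :i] = 0.5 * (A[s, :i] + A[d, :i])
            A[i, i] = 1.0 + 0.5 * A[s, d]
        elif s >= 0 or d >= 0:
            k = s if s >= 0 else d
            A[i, :i] = 0.5 * A[k, :i]
            A[i, i] = 1.0
        else:
            A[i, i] = 1.0
        A[:i, i] = A[i, :i]
    return A


def genomic_G(
    genotypes: GenotypeMatrix,
    blend_alpha: float = 0.95,
    A22: Optional[np.ndarray] = None,
    tune: bool = True,
) -> np.ndarray:
    """VanRaden method-1 genomic relationship matrix.

    G0 = Z Z' / (2 sum p_k (1 - p_k)) with Z the allele counts centred by
    twice the observed frequencies and missing calls imputed to the SNP
    mean. If ``tune`` and A22 is given, G0 is rescaled (a + b*G0) so its
    mean diagonal and mean off-diagonal match A22; it is then blended as
    blend_alpha * G0 + (1 - blend_alpha) * A22.
    """
    freq = genotypes.allele_freqs()
    if np.any(freq <= 0) or np.any(freq >= 1):
        raise ValueError("monomorphic SNP after QC; remove it before building G")
    M = genotypes.calls.astype(float)
    miss = genotypes.calls == MISSING
    M[miss] = np.broadcast_to(2 * freq, M.shape)[miss]  # mean imputation
    Z = M - 2 * freq
    denom = 2.0 * np.sum(freq * (1.0 - freq))
    G = (Z @ Z.T) / denom

    if A22 is not None and tune:
        n = G.shape[0]
        off = ~np.eye(n, dtype=bool)
        # solve mean(diag(a + bG)) = mean(diag(A22)), same for off-diagonals
        gd, go = G.diagonal().mean(), G[off].mean() if n > 1 else 0.0
        ad, ao = A22.diagonal().mean(), A22[off].mean() if n > 1 else 0.0
        if abs(gd - go) > 1e-12:
            b = (ad - ao) / (gd - go)
            a = ad - b * gd
            G = a + b * G
    if A22 is not None and blend_alpha < 1.0:
        G = blend_alpha * G + (1.0 - blend_alpha) * A22
    return G


def h_inverse(A: np.ndarray, G: np.ndarray, genotyped_index: Sequence[int]) -> np.ndarray:
    """Single-step H^-1 = A^-1 + [[0,0],[0, G^-1 - A22^-1]] (tau = omega = 1)."""
    idx = np.asarray(genotyped_index, dtype=np.int64)
    A_inv = np.linalg.inv(A)
    if len(idx) == 0:
        return A_inv
    A22 = A[np.ix_(idx, idx)]
    try:
        G_inv = np.linalg.inv(G)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "G is singular; blend it with A22 (blend_alpha < 1) before inverting"
        ) from err
    H_inv = A_inv.copy()
    H_inv[np.ix_(idx, idx)] += G_inv - np.linalg.inv(A22)
    return 0.5 * (H_inv + H_inv.T)


def build_relationships(
    pedigree: pd.DataFrame,
    genotypes: Optional[GenotypeMatrix] = None,
    blend_alpha: float = 0.95,
    tune: bool = True,
) -> RelationshipSet:
    """Assemble A (always) and, when genotypes are given, G and H^-1."""
    A = pedigree_A(pedigree)
    ids = pedigree["animal_id"].to_numpy()
    if genotypes is None or genotypes.n_animals == 0:
        return RelationshipSet(
            animal_ids=ids, A=A, genotyped_index=np.array([], dtype=np.int64),
            H_inv=np.linalg.inv(A), _H=A,
        )
    pos = {a: i for i, a in enumerate(ids)}
    gidx = np.array([pos[a] for a in genotypes.animal_ids], dtype=np.int64)
    A22 = A[np.ix_(gidx, gidx)]
    G = genomic_G(genotypes, blend_alpha=blend_alpha, A22=A22, tune=tune)
    Hinv = h_inverse(A, G, gidx)
    return RelationshipSet(animal_ids=ids, A=A, genotyped_index=gidx, A22=A22, G=G, H_inv=Hinv)


# -- plain-text IO -----------------------------------------------------------

def write_matrix_coo(path, M: np.ndarray, ids: Sequence, id_map_path=None) -> None:
    """Write the lower triangle of a symmetric matrix as 'i j value' text
    (1-based indices), plus an optional id map file."""
    M = np.asarray(M)
    i, j = np.tril_indices(M.shape[0])
    with open(path, "w") as fh:
        for a, b in zip(i, j):
            fh.write(f"{a + 1} {b + 1} {M[a, b]!r}\n")
    if id_map_path is not None:
        with open(id_map_path, "w") as fh:
            for k, aid in enumerate(ids, start=1):
                fh.write(f"{k} {aid}\n")


def read_matrix_coo(path, n: int) -> np.ndarray:
    M = np.zeros((n, n))
    with open(path) as fh:
        for line in fh:
            a, b, v = line.split()
            M[int(a) - 1, int(b) - 1] = float(v)
            M[int(b) - 1, int(a) - 1] = float(v)
    return M


def write_genotype_tsv(path, genotypes: GenotypeMatrix) -> None:
    arr = genotypes.calls.astype(object)
    arr[genotypes.calls == MISSING] = "NA"
    df = pd.DataFrame(arr, index=genotypes.animal_ids, columns=genotypes.snp_ids)
    df.to_csv(path, sep="\t", index_label="animal_id")


def read_genotype_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values="NA")
    calls = df.to_numpy(dtype=float)
    calls = np.where(np.isnan(calls), MISSING, calls).astype(np.int8)
    return GenotypeMatrix(df.index.to_numpy(), df.columns.to_numpy(), calls)


def read_plink_raw(path) -> GenotypeMatrix:
    """Read the PLINK .raw additive-dosage dialect (IID + one column per SNP)."""
    df = pd.read_csv(path, sep=r"\s+")
    meta = [c for c in ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE") if c in df.columns]
    snp_cols = [c for c in df.columns if c not in meta]
    calls = df[snp_cols].to_numpy(dtype=float)
    calls = np.where(np.isnan(calls), MISSING, calls).astype(np.int8)
    ids = df["IID"].to_numpy() if "IID" in df.columns else df.index.to_numpy()
    return GenotypeMatrix(ids, np.array(snp_cols), calls)
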