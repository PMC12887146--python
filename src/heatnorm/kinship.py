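"""Relationship matrices for single-step evaluation.

Builds the pedigree numerator relationship matrix A (tabular method, with
inbreeding), its sparse inverse from the Henderson rules with Mendelian
sampling variances ``1/2 - (F_s + F_d)/4``, the genomic relationship matrix

    G = Z D Z' / sum_i 2 p_i (1 - p_i),   Z = M - 2p,

(VanRaden centering; D a per-SNP weight vector), the blended
``G_b = w G + (1 - w) A22`` that guarantees invertibility, and the
single-step inverse

    H^-1 = A^-1 + [0 0; 0 G_b^-1 - A22^-1]

on the genotyped block.  Genotype quality control applies the marker filters
(unmapped, duplicated position, non-autosomal, call rate, MAF, departure of
observed heterozygosity from Hardy-Weinberg expectation) and the sample
call-rate filter, all evaluated on the raw input statistics and applied
jointly so the survivor set is order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

MISSING = -1  # missing dosage code


@dataclass
class Pedigree:
    """Topologically ordered pedigree with integer parent indices (-1 unknown)."""

    ids: np.ndarray
    sire: np.ndarray  # index into ids, -1 = unknown
    dam: np.ndarray

    def __post_init__(self):
        self.ids = np.asarray(self.ids)
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        n = len(self.ids)
        if len(self.sire) != n or len(self.dam) != n:
            raise ValueError("ids/sire/dam length mismatch")
        idx = np.arange(n)
        if np.any(self.sire >= idx) or np.any(self.dam >= idx):
            raise ValueError("parents must precede offspring (pedigree not sorted)")
        self._index = {a: i for i, a in enumerate(self.ids)}

    def __len__(self):
        return len(self.ids)

    def indices_of(self, animals) -> np.ndarray:
        return np.array([self._index[a] for a in animals], dtype=np.int64)

    @property
    def is_founder(self) -> np.ndarray:
        return (self.sire < 0) & (self.dam < 0)

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, animal="animal", sire="sire", dam="dam"
    ) -> "Pedigree":
        """Build from an (animal, sire, dam) table; 0/NA = unknown parent.

        Rows are topologically sorted; unknown ancestors referenced as
        parents are appended as founders.
        """
        df = frame[[animal, sire, dam]].copy()

        def norm(x):
            if pd.isna(x) or str(x) == "0":
                return None
            return x

        entries = {
            r[0]: (norm(r[1]), norm(r[2])) for r in df.itertuples(index=False)
        }
        for a, (s, d) in list(entries.items()):
            for p in (s, d):
                if p is not None and p not in entries:
                    entries[p] = (None, None)
        order: list = []
        state: dict = {}

        def visit(a):
            st = state.get(a, 0)
            if st == 1:
                raise ValueError(f"cyclic pedigree at {a!r}")
            if st == 2:
                return
            state[a] = 1
            s, d = entries[a]
            if s is not None:
                visit(s)
            if d is not None:
                visit(d)
            state[a] = 2
            order.append(a)

        for a in entries:
            visit(a)
        pos = {a: i for i, a in enumerate(order)}
        sire_ix = np.array(
            [pos[entries[a][0]] if entries[a][0] is not None else -1 for a in order]
        )
        dam_ix = np.array(
            [pos[entries[a][1]] if entries[a][1] is not None else -1 for a in order]
        )
        return cls(np.asarray(order, dtype=object), sire_ix, dam_ix)

    def to_frame(self) -> pd.DataFrame:
        def name(ix):
            return np.where(ix >= 0, self.ids[np.maximum(ix, 0)], 0)

        return pd.DataFrame(
            {"animal": self.ids, "sire": name(self.sire), "dam": name(self.dam)}
        )


def build_A(ped: Pedigree) -> np.ndarray:
    """Numerator relationship matrix by the tabular method (with inbreeding)."""
    n = len(ped)
    A = np.zeros((n, n))
    s, d = ped.sire, ped.dam
    for i in range(n):
        si, di = s[i], d[i]
        row = np.zeros(i)
        if si >= 0:
            row += 0.5 * A[si, :i]
        if di >= 0:
            row += 0.5 * A[di, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[si, di] if si >= 0 and di >= 0 else 0.0)
    return A


def inbreeding(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients F (diagonal of A minus one)."""
    return np.diag(build_A(ped)) - 1.0


def build_A_inverse(
    ped: Pedigree, F: np.ndarray | None = None
) -> tuple[sp.csr_matrix, np.ndarray]:
    """Sparse A^-1 from the direct rules with inbreeding.

    The Mendelian sampling variance of animal i is ``0.5 - 0.25 (F_s + F_d)``
    with both parents known, ``0.75 - 0.25 F_p`` with one, and 1 for
    founders.  Returns (A^-1 as CSR, F).
    """
    n = len(ped)
    if F is None:
        F = inbreeding(ped)
    rows, cols, vals = [], [], []
    s, d = ped.sire, ped.dam
    for i in range(n):
        si, di = s[i], d[i]
        if si >= 0 and di >= 0:
            mend = 0.5 - 0.25 * (F[si] + F[di])
        elif si >= 0 or di >= 0:
            p = si if si >= 0 else di
            mend = 0.75 - 0.25 * F[p]
        else:
            mend = 1.0
        a = 1.0 / mend
        rows.append(i), cols.append(i), vals.append(a)
        for p in (si, di):
            if p >= 0:
                rows += [i, p, p]
                cols += [p, i, p]
                vals += [-a / 2, -a / 2, a / 4]
        if si >= 0 and di >= 0:
            rows += [si, di]
            cols += [di, si]
            vals += [a / 4, a / 4]
    Ainv = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    Ainv.sum_duplicates()
    return Ainv, F


@dataclass
class GenotypeMatrix:
    """Biallelic SNP dosages (0/1/2, -1 missing) with a marker map."""

    ids: np.ndarray
    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    X: np.ndarray  # (n_animals, n_snps), int8

    def __post_init__(self):
        self.X = np.asarray(self.X)
        if self.X.shape != (len(self.ids), len(self.snp_ids)):
            raise ValueError("dosage matrix shape inconsistent with ids/map")

    @property
    def n_animals(self) -> int:
        return len(self.ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def allele_freq(self) -> np.ndarray:
        """Per-SNP frequency of the counted allele, over non-missing calls."""
        X = self.X
        obs = X != MISSING
        with np.errstate(invalid="ignore"):
            p = np.where(X == MISSING, 0, X).sum(axis=0) / (2.0 * obs.sum(axis=0))
        return p

    def subset(self, animal_mask=None, snp_mask=None) -> "GenotypeMatrix":
        am = np.ones(self.n_animals, bool) if animal_mask is None else animal_mask
        sm = np.ones(self.n_snps, bool) if snp_mask is None else snp_mask
        return GenotypeMatrix(
            self.ids[am], self.snp_ids[sm], self.chrom[sm], self.pos[sm],
            self.X[np.ix_(am, sm)],
        )


def genotype_qc(
    geno: GenotypeMatrix,
    snp_call_rate: float = 0.90,
    maf: float = 0.05,
    hwe_dev: float = 0.15,
    sample_call_rate: float = 0.90,
    autosomes: set | None = None,
) -> tuple[GenotypeMatrix, dict]:
    """Marker and sample quality control, all filters on raw input statistics.

    Marker filters: unmapped (chrom/pos <= 0 or NA); duplicated chrom:pos;
    non-autosomal (when ``autosomes`` given); call rate < ``snp_call_rate``;
    MAF < ``maf``; |observed het. freq - 2p(1-p)| > ``hwe_dev``.  Samples
    must have call rate > ``sample_call_rate``.
    """
    X = geno.X
    obs = X != MISSING
    n_anim, n_snp = X.shape

    chrom_num = pd.to_numeric(pd.Series(geno.chrom), errors="coerce")
    pos_num = pd.to_numeric(pd.Series(geno.pos), errors="coerce")
    mapped = chrom_num.notna().to_numpy() & (pos_num.fillna(0) > 0).to_numpy()
    key = pd.Series([f"{c}:{p}" for c, p in zip(geno.chrom, geno.pos)])
    duplicated = key.duplicated(keep="first").to_numpy()
    if autosomes is not None:
        autosomal = np.array([c in autosomes for c in geno.chrom])
    else:
        autosomal = np.ones(n_snp, bool)
    call = obs.mean(axis=0)
    p = geno.allele_freq()
    maf_val = np.minimum(p, 1 - p)
    het_obs = np.where(obs, X == 1, False).sum(axis=0) / np.maximum(obs.sum(axis=0), 1)
    hwe = np.abs(het_obs - 2 * p * (1 - p))

    filters = {
        "unmapped": ~mapped,
        "duplicated": duplicated,
        "not_autosomal": ~autosomal,
        "call_rate": call < snp_call_rate,
        "maf": maf_val < maf,
        "hwe_deviation": hwe > hwe_dev,
    }
    snp_fail = np.zeros(n_snp, bool)
    report = {}
    for name, mask in filters.items():
        report[f"snp_{name}"] = int(mask.sum())
        snp_fail |= mask

    sample_call = obs.mean(axis=1)
    sample_fail = ~(sample_call > sample_call_rate)
    report["sample_call_rate"] = int(sample_fail.sum())

    out = geno.subset(~sample_fail, ~snp_fail)
    report["snp_removed"] = int(snp_fail.sum())
    report["snp_kept"] = out.n_snps
    report["sample_kept"] = out.n_animals
    return out, report


def center_dosages(geno: GenotypeMatrix, p: np.ndarray | None = None) -> np.ndarray:
    """Z = M - 2p with missing calls imputed at the mean (0 after centering)."""
    if p is None:
        p = geno.allele_freq()
    X = geno.X.astype(float)
    X[geno.X == MISSING] = np.nan
    Z = X - 2.0 * p
    return np.nan_to_num(Z, nan=0.0)


def build_G(
    geno: GenotypeMatrix,
    weights: np.ndarray | None = None,
    p: np.ndarray | None = None,
) -> np.ndarray:
    """Weighted genomic relationship matrix G = Z D Z' / sum 2p(1-p)."""
    if p is None:
        p = geno.allele_freq()
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("monomorphic SNP present; run genotype_qc first")
    Z = center_dosages(geno, p)
    k = float(np.sum(2.0 * p * (1.0 - p)))
    if weights is None:
        return (Z @ Z.T) / k
    D = np.asarray(weights, dtype=float)
    if D.shape != (geno.n_snps,) or np.any(D < 0):
        raise ValueError("weights must be a non-negative vector of length n_snps")
    return (Z * D) @ Z.T / k


def blend_G(G: np.ndarray, A22: np.ndarray, weight: float = 0.95) -> np.ndarray:
    """G_b = w G + (1-w) A22, the standard invertibility blend."""
    if not 0.0 < weight <= 1.0:
        raise ValueError("blend weight must be in (0, 1]")
    return weight * G + (1.0 - weight) * A22


@dataclass
class RelationshipSet:
    """All matrices needed by a single-step evaluation, with id bookkeeping."""

    ped: Pedigree
    A_inv: sp.csr_matrix
    F: np.ndarray
    genotyped_index: np.ndarray | None = None  # positions in pedigree order
    A22: np.ndarray | None = None
    G: np.ndarray | None = None
    G_blend: np.ndarray | None = None
    H_inv: sp.csr_matrix = field(default=None)

    @property
    def kinv(self) -> sp.csr_matrix:
        """The relationship inverse to use in the MME (H^-1 if genomic)."""
        return self.H_inv if self.H_inv is not None else self.A_inv


def build_H_inverse(
    A_inv: sp.spmatrix,
    A22: np.ndarray,
    G_blend: np.ndarray,
    genotyped_index: np.ndarray,
) -> sp.csr_matrix:
    """H^-1 = A^-1 + [0 0; 0 G_b^-1 - A22^-1] on the genotyped block."""
    g = np.asarray(genotyped_index, dtype=np.int64)
    if len(g) == 0:
        return sp.csr_matrix(A_inv)
    if G_blend.shape != A22.shape or G_blend.shape[0] != len(g):
        raise ValueError("G/A22 dimensions inconsistent with genotyped index")
    delta = np.linalg.inv(G_blend) - np.linalg.inv(A22)
    block = sp.coo_matrix(
        (delta.ravel(), (np.repeat(g, len(g)), np.tile(g, len(g)))),
        shape=A_inv.shape,
    )
    H_inv = (sp.csr_matrix(A_inv) + block.tocsr()).tocsr()
    return H_inv


def relationship_set(
    ped: Pedigree,
    geno: GenotypeMatrix | None = None,
    weights: np.ndarray | None = None,
    blend_weight: float = 0.95,
) -> RelationshipSet:
    """Build A^-1 and, when genotypes are given, G, the blend and H^-1."""
    Ainv, F = build_A_inverse(ped)
    rs = RelationshipSet(ped=ped, A_inv=Ainv, F=F)
    if geno is None or geno.n_animals == 0:
        return rs
    gi = ped.indices_of(geno.ids)
    A = build_A(ped)
    A22 = A[np.ix_(gi, gi)]
    G = build_G(geno, weights=weights)
    Gb = blend_G(G, A22, blend_weight)
    rs.genotyped_index = gi
    rs.A22 = A22
    rs.G = G
    rs.G_blend = Gb
    rs.H_inv = build_H_inverse(Ainv, A22, Gb, gi)
    return rs


def read_plink_raw(raw_path, map_path) -> GenotypeMatrix:
    """Read PLINK-style .raw (whitespace table with IID + SNP columns) + .map."""
    raw = pd.read_csv(raw_path, sep=r"\s+")
    mp = pd.read_csv(
        map_path, sep=r"\s+", header=None, names=["chrom", "snp_id", "cm", "pos"]
    )
    id_col = "IID" if "IID" in raw.columns else raw.columns[0]
    meta = {"FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"}
    snp_cols = [c for c in raw.columns if c not in meta]
    X = raw[snp_cols].to_numpy()
    X = np.where(np.isnan(X.astype(float)), MISSING, X).astype(np.int8)
    snp_ids = np.array([c.rsplit("_", 1)[0] if "_" in c else c for c in snp_cols])
    mp = mp.set_index("snp_id").loc[snp_ids]
    return GenotypeMatrix(
        ids=raw[id_col].to_numpy(),
        snp_ids=snp_ids,
        chrom=mp["chrom"].to_numpy(),
        pos=mp["pos"].to_numpy(),
        X=X,
    )
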