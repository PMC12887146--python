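"""Weighted single-step GWAS on the heat-tolerance slope.

SNP effects are back-solved from the genomic-level breeding values of the
reaction-norm slope coefficient:

    u-hat = D Z' G^-1 a_g / k,     k = sum_i 2 p_i (1 - p_i),

where Z is the centred dosage matrix, D the per-SNP weight vector and a_g
the slope breeding values of the genotyped animals.  Weights are iterated
(d_i proportional to u_i^2 2 p_i (1 - p_i), rescaled to sum to the SNP
count), G is rebuilt and the model re-solved; two iterations by default.
Five-SNP sliding windows are scored by the share of the genomic slope
variance Var(Z_w u_w) / Var(Z u); windows above 1% are merged into
candidate regions and genes within 200 kb are attached.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import kinship
from .kinship import GenotypeMatrix
from .rnm import GeneticCovariances, ModelFrame, solve_mme

SLOPE_INDEX = 5  # delta_1, the THI linear coefficient


def backsolve_snp_effects(
    slope_gebv: np.ndarray,
    G: np.ndarray,
    Z: np.ndarray,
    weights: np.ndarray | None,
    p: np.ndarray,
) -> np.ndarray:
    """SNP effects u = D Z' G^-1 a_g / k from genotyped-animal slope GEBVs."""
    a = np.asarray(slope_gebv, float)
    if Z.shape[0] != len(a) or G.shape != (len(a), len(a)):
        raise ValueError("dimension mismatch between GEBVs, Z and G")
    k = float(np.sum(2.0 * p * (1.0 - p)))
    rhs = np.linalg.solve(G, a)
    u = Z.T @ rhs / k
    if weights is not None:
        u = np.asarray(weights, float) * u
    return u


def update_weights(u: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Next-iteration weights d_i ~ u_i^2 2p_i(1-p_i), rescaled to n SNPs."""
    u = np.asarray(u, float)
    raw = u**2 * 2.0 * p * (1.0 - p)
    total = raw.sum()
    if total == 0:
        warnings.warn("all SNP effects zero; keeping uniform weights")
        return np.ones_like(raw)
    return raw * (len(raw) / total)


@dataclass
class WssgwasIteration:
    weights: np.ndarray
    snp_effects: np.ndarray
    windows: pd.DataFrame


def window_variance(
    u: np.ndarray,
    Z: np.ndarray,
    snp_map: pd.DataFrame,
    window: int = 5,
    stride: int = 1,
) -> pd.DataFrame:
    """Share of genomic slope variance per sliding window of SNPs.

    ``snp_map`` needs columns ``snp_id, chrom, pos`` in the column order of
    ``Z``; SNPs must be sorted by chromosome then position.  Windows never
    cross chromosomes; chromosomes with fewer than ``window`` SNPs emit no
    windows.  Shares are Var(Z_w u_w) / Var(Z u) x 100 over the genotyped
    animals.
    """
    u = np.asarray(u, float)
    total = Z @ u
    denom = float(np.var(total))
    if denom == 0:
        raise ValueError("total genomic slope variance is zero")
    chroms = snp_map["chrom"].to_numpy()
    pos = snp_map["pos"].to_numpy()
    rows = []
    for chrom in pd.unique(chroms):
        ix = np.where(chroms == chrom)[0]
        if np.any(np.diff(pos[ix]) < 0):
            raise ValueError(f"SNPs not position-sorted on chromosome {chrom}")
        if len(ix) < window:
            continue
        for s in range(0, len(ix) - window + 1, stride):
            w_ix = ix[s : s + window]
            share = float(np.var(Z[:, w_ix] @ u[w_ix])) / denom * 100.0
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(pos[w_ix[0]]),
                    "end": int(pos[w_ix[-1]]),
                    "first_snp": snp_map["snp_id"].iloc[w_ix[0]],
                    "last_snp": snp_map["snp_id"].iloc[w_ix[-1]],
                    "share_pct": share,
                    "snp_indices": list(w_ix),
                }
            )
    return pd.DataFrame(rows)


def call_regions(windows: pd.DataFrame, threshold: float = 1.0) -> pd.DataFrame:
    """Windows above the variance-share threshold, merged when overlapping.

    Returns regions with 1-based inclusive bounds, the peak window share and
    the member SNP indices.
    """
    if len(windows) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "share_pct", "snp_indices"])
    qual = windows[windows["share_pct"] > threshold].sort_values(["chrom", "start"])
    regions = []
    for _, w in qual.iterrows():
        if (
            regions
            and regions[-1]["chrom"] == w["chrom"]
            and w["start"] <= regions[-1]["end"]
        ):
            regions[-1]["end"] = max(regions[-1]["end"], w["end"])
            regions[-1]["share_pct"] = max(regions[-1]["share_pct"], w["share_pct"])
            regions[-1]["snp_indices"] = sorted(
                set(regions[-1]["snp_indices"]) | set(w["snp_indices"])
            )
        else:
            regions.append(
                {
                    "chrom": w["chrom"],
                    "start": int(w["start"]),
                    "end": int(w["end"]),
                    "share_pct": float(w["share_pct"]),
                    "snp_indices": list(w["snp_indices"]),
                }
            )
    return pd.DataFrame(regions)


def annotate_genes(
    regions: pd.DataFrame, genes: pd.DataFrame, flank: int = 200_000
) -> pd.DataFrame:
    """Attach genes whose span intersects region +/- ``flank`` (closed, 1-based).

    ``genes`` needs columns ``chrom, start, end, name``.  Chromosome labels
    are normalised by stripping a leading 'chr'.
    """
    def norm(c):
        c = str(c)
        return c[3:] if c.lower().startswith("chr") else c

    out = regions.copy()
    hits = []
    gchrom = genes["chrom"].map(norm).to_numpy()
    for _, r in out.iterrows():
        rc = norm(r["chrom"])
        lo, hi = r["start"] - flank, r["end"] + flank
        sel = (gchrom == rc) & (genes["end"] >= lo) & (genes["start"] <= hi)
        hits.append(list(genes.loc[sel, "name"]))
    out["genes"] = hits
    return out


def read_gene_table(path) -> pd.DataFrame:
    """Gene annotation from BED (0-based half-open, converted), GFF3 or TSV.

    Returns 1-based inclusive ``chrom, start, end, name``.
    """
    path = str(path)
    if path.endswith(".bed"):
        import pyranges as pr

        df = pr.read_bed(path).df
        out = df.rename(
            columns={"Chromosome": "chrom", "Start": "start", "End": "end", "Name": "name"}
        )[["chrom", "start", "end", "name"]].copy()
        out["start"] = out["start"] + 1  # to 1-based inclusive
        return out
    if path.endswith((".gff", ".gff3")):
        import pyranges as pr

        df = pr.read_gff3(path).df
        df = df[df["Feature"] == "gene"] if "Feature" in df.columns else df
        name = df["Name"] if "Name" in df.columns else df.get("ID", df.index.astype(str))
        out = pd.DataFrame(
            {
                "chrom": df["Chromosome"],
                "start": df["Start"] + 1,
                "end": df["End"],
                "name": name,
            }
        )
        return out.reset_index(drop=True)
    df = pd.read_csv(path, sep="\t")
    need = {"chrom", "start", "end", "name"}
    if not need.issubset(df.columns):
        raise ValueError(f"gene TSV must carry columns {sorted(need)}")
    return df


@dataclass
class WssgwasResult:
    iterations: list[WssgwasIteration] = field(default_factory=list)
    regions: pd.DataFrame | None = None

    @property
    def final(self) -> WssgwasIteration:
        return self.iterations[-1]


def run_wssgwas(
    frame: ModelFrame,
    covs: GeneticCovariances,
    geno: GenotypeMatrix,
    n_iterations: int = 2,
    threshold: float = 1.0,
    window: int = 5,
    stride: int = 1,
    blend_weight: float = 0.95,
    genes: pd.DataFrame | None = None,
    flank: int = 200_000,
) -> WssgwasResult:
    """Iterated single-step GWAS on the reaction-norm slope.

    Iteration 1 uses uniform weights; each subsequent iteration rebuilds the
    weighted G, re-solves the mixed-model equations under H^-1 and
    back-solves SNP effects; exactly ``n_iterations`` back-solves are
    performed.  Window shares, called regions and (when a gene table is
    given) annotations come from the final iteration.
    """
    ped = frame.ped
    gi = ped.indices_of(geno.ids)
    A = kinship.build_A(ped)
    A22 = A[np.ix_(gi, gi)]
    Ainv, _ = kinship.build_A_inverse(ped)
    p = geno.allele_freq()
    Z = kinship.center_dosages(geno, p)
    snp_map = pd.DataFrame(
        {"snp_id": geno.snp_ids, "chrom": geno.chrom, "pos": geno.pos}
    )
    D = np.ones(geno.n_snps)
    result = WssgwasResult()
    for _ in range(n_iterations):
        G = kinship.build_G(geno, weights=D, p=p)
        Gb = kinship.blend_G(G, A22, blend_weight)
        Hinv = kinship.build_H_inverse(Ainv, A22, Gb, gi)
        sol = solve_mme(frame, covs, Hinv)
        a_slope = sol.additive[gi, SLOPE_INDEX]
        u = backsolve_snp_effects(a_slope, Gb, Z, D, p)
        windows = window_variance(u, Z, snp_map, window=window, stride=stride)
        result.iterations.append(
            WssgwasIteration(weights=D.copy(), snp_effects=u, windows=windows)
        )
        D = update_weights(u, p)
    regions = call_regions(result.final.windows, threshold=threshold)
    if genes is not None and len(regions):
        regions = annotate_genes(regions, genes, flank=flank)
    result.regions = regions
    return result
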