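"""Random-regression reaction-norm animal model.

The observation model for a test-day milk yield record is

    y = FIXED + sum_n beta_n w_n(d) + sum_n gamma_n w_n(d)
              + sum_n delta_n w_n(t) + sum_n eps_n w_n(t) + e,

with w_n orthonormal Legendre polynomials of standardised days in milk d
(order 3: intercept, linear, quadratic, cubic) and of standardised THI t
(order 1: intercept and slope -- a classical reaction norm).  Additive
coefficients (beta, delta) are correlated across animals through the
pedigree (A) or single-step hybrid (H) relationship matrix and carry a
joint 6x6 covariance matrix; permanent-environment coefficients (gamma,
eps) are i.i.d. per recorded animal with their own joint 6x6 matrix; the
residual variance is heterogeneous over six DIM-by-THI classes.

Fixed effects: contemporary group; milking-frequency x DIM-class;
age-at-calving linear + quadratic; DIM linear/quadratic/cubic nested in
herd x two-calving-year classes; THI linear nested in DIM class.

Variance components are estimated by Gibbs sampling with inverse-Wishart
priors; best linear unbiased solutions at fixed components come from the
mixed-model equations solved by preconditioned conjugate gradients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.special import eval_legendre

from . import _gibbs

N_COEF = 6  # 4 DIM + 2 THI coefficients per animal


# --------------------------------------------------------------------------
# model specification and covariance containers
# --------------------------------------------------------------------------


@dataclass
class ModelSpec:
    """Trajectory orders, standardisation ranges and fixed-effect layout."""

    dim_order: int = 3
    thi_order: int = 1
    dim_range: tuple = (5, 305)
    thi_range: tuple = (60, 80)
    age_center: float = 41.0  # months, midpoint of the 22-60 editing window
    age_scale: float = 19.0

    @property
    def n_dim_coef(self) -> int:
        return self.dim_order + 1

    @property
    def n_thi_coef(self) -> int:
        return self.thi_order + 1


@dataclass
class GeneticCovariances:
    """Joint (co)variance structure of the random regression coefficients.

    ``G_*`` blocks form the additive 6x6 matrix [[G_dim, G_cross],
    [G_cross', G_thi]] (kg^2); ``P_*`` the permanent-environment analogue;
    ``resid_var`` holds the six residual class variances.
    """

    G_dim: np.ndarray
    G_thi: np.ndarray
    G_cross: np.ndarray
    P_dim: np.ndarray
    P_thi: np.ndarray
    P_cross: np.ndarray
    resid_var: np.ndarray

    def __post_init__(self):
        self.G_dim = np.atleast_2d(np.asarray(self.G_dim, float))
        self.G_thi = np.atleast_2d(np.asarray(self.G_thi, float))
        self.G_cross = np.asarray(self.G_cross, float).reshape(
            self.G_dim.shape[0], self.G_thi.shape[0]
        )
        self.P_dim = np.atleast_2d(np.asarray(self.P_dim, float))
        self.P_thi = np.atleast_2d(np.asarray(self.P_thi, float))
        self.P_cross = np.asarray(self.P_cross, float).reshape(
            self.P_dim.shape[0], self.P_thi.shape[0]
        )
        self.resid_var = np.asarray(self.resid_var, float)

    @property
    def joint_additive(self) -> np.ndarray:
        return np.block([[self.G_dim, self.G_cross], [self.G_cross.T, self.G_thi]])

    @property
    def joint_pe(self) -> np.ndarray:
        return np.block([[self.P_dim, self.P_cross], [self.P_cross.T, self.P_thi]])

    @classmethod
    def from_joint(cls, Ga, Pj, resid_var, n_dim=4):
        Ga = np.asarray(Ga, float)
        Pj = np.asarray(Pj, float)
        return cls(
            G_dim=Ga[:n_dim, :n_dim],
            G_thi=Ga[n_dim:, n_dim:],
            G_cross=Ga[:n_dim, n_dim:],
            P_dim=Pj[:n_dim, :n_dim],
            P_thi=Pj[n_dim:, n_dim:],
            P_cross=Pj[:n_dim, n_dim:],
            resid_var=resid_var,
        )

    def validate(self, tol: float = 1e-8):
        for name, M in (("additive", self.joint_additive), ("pe", self.joint_pe)):
            if not np.allclose(M, M.T):
                raise ValueError(f"{name} joint matrix not symmetric")
            w = np.linalg.eigvalsh(M)
            if w.min() < -tol * max(1.0, w.max()):
                raise ValueError(f"{name} joint matrix not positive semi-definite")
        if np.any(self.resid_var <= 0):
            raise ValueError("residual variances must be positive")
        return self


# --------------------------------------------------------------------------
# Legendre covariables
# --------------------------------------------------------------------------


def legendre_row(x, xmin, xmax, order):
    """Orthonormal Legendre covariable row(s) phi_0..phi_order.

    The covariate is standardised to m = 2(x - xmin)/(xmax - xmin) - 1 and
    phi_n(m) = sqrt((2n+1)/2) P_n(m).  ``x`` may be scalar or array; rows of
    the returned array correspond to elements of ``x``.
    """
    if xmin >= xmax:
        raise ValueError("xmin must be < xmax")
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    if np.any((x < xmin - 1e-9) | (x > xmax + 1e-9)):
        raise ValueError(f"covariate outside standardisation range [{xmin}, {xmax}]")
    m = 2.0 * (x - xmin) / (xmax - xmin) - 1.0
    out = np.empty((len(x), order + 1))
    for n in range(order + 1):
        out[:, n] = np.sqrt((2 * n + 1) / 2.0) * eval_legendre(n, m)
    return out[0] if scalar else out


def phi_dim(x, spec: ModelSpec):
    return legendre_row(x, *spec.dim_range, spec.dim_order)


def phi_thi(x, spec: ModelSpec):
    return legendre_row(x, *spec.thi_range, spec.thi_order)


# --------------------------------------------------------------------------
# design matrices
# --------------------------------------------------------------------------


@dataclass
class ModelFrame:
    """Design matrices and bookkeeping for one data set."""

    W: sp.csr_matrix  # [X | Z_additive | Z_pe]
    y: np.ndarray
    resid_class: np.ndarray  # 0-based
    n_fixed: int
    fixed_names: list
    ped: "object"  # kinship.Pedigree
    rec_ids: np.ndarray  # recorded animals, PE block order
    rec_index: np.ndarray  # their pedigree positions
    spec: ModelSpec

    @property
    def n_records(self) -> int:
        return len(self.y)

    @property
    def n_ped(self) -> int:
        return len(self.ped)

    @property
    def n_rec_animals(self) -> int:
        return len(self.rec_ids)

    @property
    def n_coef(self) -> int:
        return self.n_fixed + N_COEF * (self.n_ped + self.n_rec_animals)


def build_model_frame(records: pd.DataFrame, ped, spec: ModelSpec | None = None) -> ModelFrame:
    """Assemble X, Z_a, Z_p from edited records with THI and classes attached.

    ``records`` must carry ``animal, herd, date, dim, milk_kg, age_months,
    cg, dim_class, thi_class, resid_class`` (``milking_freq`` optional).
    """
    spec = spec or ModelSpec()
    need = {"animal", "herd", "date", "dim", "milk_kg", "age_months", "cg",
            "dim_class", "thi_class", "resid_class"}
    missing = need - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    df = records.reset_index(drop=True)
    n = len(df)
    y = df["milk_kg"].to_numpy(float)
    rclass = df["resid_class"].to_numpy(int) - 1

    dim = df["dim"].to_numpy(float)
    tcls = df["thi_class"].to_numpy(float)
    Phi_d = legendre_row(dim, *spec.dim_range, spec.dim_order) if n else np.zeros((0, spec.n_dim_coef))
    Phi_t = legendre_row(tcls, *spec.thi_range, spec.thi_order) if n else np.zeros((0, spec.n_thi_coef))
    m_d = 2.0 * (dim - spec.dim_range[0]) / (spec.dim_range[1] - spec.dim_range[0]) - 1.0
    m_t = 2.0 * (tcls - spec.thi_range[0]) / (spec.thi_range[1] - spec.thi_range[0]) - 1.0

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    names: list[str] = []
    ridx = np.arange(n)
    offset = 0

    def add_block(r, c, v, block_names):
        nonlocal offset
        rows.append(np.asarray(r, dtype=np.int64))
        cols.append(np.asarray(c, dtype=np.int64) + offset)
        vals.append(np.asarray(v, float))
        names.extend(block_names)
        offset += len(block_names)

    # contemporary group (full dummy set; carries the model intercept)
    cg_cat = pd.Categorical(df["cg"])
    add_block(ridx, cg_cat.codes, np.ones(n), [f"cg:{l}" for l in cg_cat.categories])

    # milking frequency x DIM class (treatment coding, first level dropped)
    mfreq = df["milking_freq"].astype(str) if "milking_freq" in df.columns else pd.Series(["2x"] * n)
    mfd = pd.Categorical(mfreq.to_numpy() + "|" + df["dim_class"].astype(str).to_numpy())
    if len(mfd.categories) > 1:
        keep = mfd.codes > 0
        add_block(
            ridx[keep], mfd.codes[keep] - 1, np.ones(int(keep.sum())),
            [f"mfreq_dimc:{l}" for l in mfd.categories[1:]],
        )

    # age at calving, linear + quadratic (standardised)
    age = (df["age_months"].to_numpy(float) - spec.age_center) / spec.age_scale
    add_block(np.tile(ridx, 2), np.repeat([0, 1], n),
              np.concatenate([age, age**2]), ["age:lin", "age:quad"])

    # DIM polynomials nested in herd x 2-calving-year classes
    dates = pd.to_datetime(df["date"])
    cyear = (dates - pd.to_timedelta(dim, unit="D")).dt.year
    h2y = pd.Categorical(df["herd"].astype(str).to_numpy() + "|" + (cyear // 2).astype(str).to_numpy())
    h2y_names = []
    h2y_r, h2y_c, h2y_v = [], [], []
    for k, lev in enumerate(h2y.categories):
        for pw in range(1, 4):
            h2y_names.append(f"h2y:{lev}:dim^{pw}")
        sel = h2y.codes == k
        for pw in range(1, 4):
            h2y_r.append(ridx[sel])
            h2y_c.append(np.full(int(sel.sum()), 3 * k + pw - 1))
            h2y_v.append(m_d[sel] ** pw)
    if h2y_names:
        add_block(np.concatenate(h2y_r), np.concatenate(h2y_c), np.concatenate(h2y_v), h2y_names)

    # THI linear nested in DIM class
    dcls = df["dim_class"].to_numpy(int)
    used = np.unique(dcls)
    dmap = {c: k for k, c in enumerate(used)}
    add_block(ridx, np.array([dmap[c] for c in dcls]), m_t,
              [f"thi_in_dimc:{c}" for c in used])

    n_fixed = offset
    X = sp.coo_matrix(
        (np.concatenate(vals) if vals else [],
         (np.concatenate(rows) if rows else [], np.concatenate(cols) if cols else [])),
        shape=(n, n_fixed),
    ).tocsr()

    # random-effect incidence: [phi(dim) | phi(thi)] per record
    phi = np.hstack([Phi_d, Phi_t])  # (n, 6)
    a_ix = ped.indices_of(df["animal"])
    rec_index = np.unique(a_ix)
    rec_pos = {p: k for k, p in enumerate(rec_index)}
    p_ix = np.array([rec_pos[p] for p in a_ix], dtype=np.int64)

    rr = np.repeat(ridx, N_COEF)
    cc_a = (N_COEF * a_ix[:, None] + np.arange(N_COEF)[None, :]).ravel()
    cc_p = (N_COEF * p_ix[:, None] + np.arange(N_COEF)[None, :]).ravel()
    vv = phi.ravel()
    Za = sp.coo_matrix((vv, (rr, cc_a)), shape=(n, N_COEF * len(ped))).tocsr()
    Zp = sp.coo_matrix((vv, (rr, cc_p)), shape=(n, N_COEF * len(rec_index))).tocsr()

    W = sp.hstack([X, Za, Zp], format="csr")
    return ModelFrame(
        W=W, y=y, resid_class=rclass, n_fixed=n_fixed, fixed_names=names,
        ped=ped, rec_ids=ped.ids[rec_index], rec_index=rec_index, spec=spec,
    )


# --------------------------------------------------------------------------
# mixed-model equations
# --------------------------------------------------------------------------


@dataclass
class SolutionSet:
    """Fixed-effect solutions and per-animal regression coefficients."""

    fixed: np.ndarray
    fixed_names: list
    additive: np.ndarray  # (n_ped, 6): beta0..beta3, delta0, delta1
    pe: np.ndarray  # (n_rec_animals, 6)
    animal_ids: np.ndarray
    rec_ids: np.ndarray

    @classmethod
    def from_theta(cls, theta: np.ndarray, frame: ModelFrame) -> "SolutionSet":
        nf = frame.n_fixed
        na = N_COEF * frame.n_ped
        return cls(
            fixed=theta[:nf],
            fixed_names=frame.fixed_names,
            additive=theta[nf : nf + na].reshape(frame.n_ped, N_COEF),
            pe=theta[nf + na :].reshape(frame.n_rec_animals, N_COEF),
            animal_ids=frame.ped.ids,
            rec_ids=frame.rec_ids,
        )


def assemble_mme(frame: ModelFrame, covs: GeneticCovariances, kinv: sp.spmatrix):
    """Coefficient matrix and right-hand side of Henderson's MME."""
    covs.validate()
    rinv = 1.0 / covs.resid_var[frame.resid_class]
    W = frame.W
    Rinv = sp.diags(rinv)
    C_data = (W.T @ Rinv @ W).tocsr()
    Ga_inv = np.linalg.inv(covs.joint_additive)
    P_inv = np.linalg.inv(covs.joint_pe)
    Qa = sp.kron(sp.csr_matrix(kinv), Ga_inv, format="csr")
    Qp = sp.kron(sp.identity(frame.n_rec_animals, format="csr"), P_inv, format="csr")
    Q = sp.block_diag(
        [sp.csr_matrix((frame.n_fixed, frame.n_fixed)), Qa, Qp], format="csr"
    )
    C = (C_data + Q).tocsr()
    rhs = W.T @ (rinv * frame.y)
    return C, rhs


def solve_mme(
    frame: ModelFrame,
    covs: GeneticCovariances,
    kinv: sp.spmatrix,
    tol: float = 1e-8,
    maxiter: int | None = None,
) -> SolutionSet:
    """Solve the MME at fixed (co)variances by preconditioned CG.

    Converges to relative residual <= ``tol``; falls back to a sparse direct
    solve if CG stalls.  Raises on aliased (zero-diagonal) fixed-effect
    columns.
    """
    C, rhs = assemble_mme(frame, covs, kinv)
    diag = C.diagonal()
    if np.any(diag[: frame.n_fixed] <= 0):
        bad = [frame.fixed_names[i] for i in np.where(diag[: frame.n_fixed] <= 0)[0]]
        raise ValueError(f"aliased fixed-effect columns: {bad[:10]}")
    M = sp.diags(1.0 / diag)
    maxiter = maxiter or max(2000, 20 * C.shape[0])
    theta, info = spla.cg(C, rhs, rtol=tol * 1e-2, atol=0.0, M=M, maxiter=maxiter)
    rel = np.linalg.norm(C @ theta - rhs) / max(np.linalg.norm(rhs), 1e-300)
    if info != 0 or rel > tol:
        warnings.warn(f"CG stalled (rel residual {rel:.2e}); using direct solve")
        theta = spla.spsolve(C.tocsc(), rhs)
    return SolutionSet.from_theta(theta, frame)


# --------------------------------------------------------------------------
# Gibbs sampling
# --------------------------------------------------------------------------


@dataclass
class ChainConfig:
    """Gibbs chain bookkeeping: total length, burn-in and thinning."""

    length: int = 1_000_000
    burn_in: int = 600_000
    thin: int = 100

    def __post_init__(self):
        if self.length <= self.burn_in:
            raise ValueError("chain length must exceed burn-in")
        if self.thin < 1:
            raise ValueError("thinning interval must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.length - self.burn_in) // self.thin


@dataclass
class Priors:
    """Inverse-Wishart scales/df for the 6x6 blocks; scaled-inv-chi2 residual."""

    S_additive: np.ndarray
    df_additive: float
    S_pe: np.ndarray
    df_pe: float
    s_resid: np.ndarray
    df_resid: float


def default_priors(y: np.ndarray) -> Priors:
    """Weakly informative priors from the phenotypic variance heuristic.

    Minimal proper inverse-Wishart degrees of freedom (dim + 2 = 8) with a
    diagonal scale of one tenth of the raw phenotypic variance; residual
    scale half the phenotypic variance with 4 df.
    """
    vy = float(np.var(np.asarray(y, float))) or 1.0
    return Priors(
        S_additive=0.1 * vy * np.eye(N_COEF),
        df_additive=N_COEF + 2.0,
        S_pe=0.1 * vy * np.eye(N_COEF),
        df_pe=N_COEF + 2.0,
        s_resid=np.full(6, 0.5 * vy),
        df_resid=4.0,
    )


@dataclass
class PosteriorChain:
    """Retained covariance-component samples with convergence diagnostics."""

    config: ChainConfig
    additive: np.ndarray  # (S, 6, 6)
    pe: np.ndarray  # (S, 6, 6)
    resid: np.ndarray  # (S, 6)

    @property
    def n_retained(self) -> int:
        return self.additive.shape[0]

    def mean_covariances(self) -> GeneticCovariances:
        return GeneticCovariances.from_joint(
            self.additive.mean(axis=0), self.pe.mean(axis=0), self.resid.mean(axis=0)
        )

    def scalar_params(self):
        """Yield (name, sample-vector) for every monitored scalar."""
        for r in range(N_COEF):
            for c in range(r, N_COEF):
                yield f"Ga[{r},{c}]", self.additive[:, r, c]
        for r in range(N_COEF):
            for c in range(r, N_COEF):
                yield f"P[{r},{c}]", self.pe[:, r, c]
        for o in range(6):
            yield f"sigma2_e[{o + 1}]", self.resid[:, o]

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, x in self.scalar_params():
            lo, hi = hpd_interval(x)
            rows.append(
                {
                    "param": name,
                    "mean": x.mean(),
                    "sd": x.std(ddof=1),
                    "hpd_low": lo,
                    "hpd_high": hi,
                    "geweke_z": geweke_z(x),
                    "ess": effective_sample_size(x),
                }
            )
        return pd.DataFrame(rows).set_index("param")

    def save(self, path):
        np.savez_compressed(
            path, additive=self.additive, pe=self.pe, resid=self.resid,
            config=np.array([self.config.length, self.config.burn_in, self.config.thin]),
        )

    @classmethod
    def load(cls, path) -> "PosteriorChain":
        z = np.load(path)
        cfg = ChainConfig(*(int(v) for v in z["config"]))
        return cls(config=cfg, additive=z["additive"], pe=z["pe"], resid=z["resid"])


def _expand_block_entries(rows_anim, cols_anim, offset):
    """Expand animal-level (i, j) entries to 6x6 coefficient-level entries."""
    six = np.arange(N_COEF)
    r = (offset + N_COEF * rows_anim[:, None, None] + six[None, :, None] + 0 * six[None, None, :])
    c = (offset + N_COEF * cols_anim[:, None, None] + 0 * six[None, :, None] + six[None, None, :])
    return r.ravel(), c.ravel()


def gibbs_sample(
    frame: ModelFrame,
    kinv: sp.spmatrix,
    chain: ChainConfig,
    priors: Priors | None = None,
    seed: int = 0,
    intercept_swap: bool = True,
) -> tuple[PosteriorChain, SolutionSet]:
    """Estimate (co)variance components and posterior-mean solutions.

    ``kinv`` is A^-1 (pedigree-only) or H^-1 (single-step).  The chain is
    reproducible given ``seed``.  ``intercept_swap`` enables the
    likelihood-invariant Gibbs move that resamples the split between the
    DIM and THI trajectory intercepts from its prior conditional (the two
    intercepts enter the likelihood only through their sum); it requires a
    dense Cholesky of the relationship covariance and dramatically improves
    mixing of the level-variance components.
    """
    priors = priors or default_priors(frame.y)
    W = frame.W.tocsr()
    n_fixed, n_ped, n_rec = frame.n_fixed, frame.n_ped, frame.n_rec_animals
    ncoef = frame.n_coef
    rclass = frame.resid_class.astype(np.int64)

    # per-residual-class cross products and RHS components
    Ms = []
    rhs_cls = np.zeros((6, ncoef))
    for o in range(6):
        selr = np.where(rclass == o)[0]
        Wo = W[selr]
        Ms.append((Wo.T @ Wo).tocsr())
        rhs_cls[o] = Wo.T @ frame.y[selr]

    K = sp.csr_matrix(kinv)
    K.sum_duplicates()
    Kcoo = K.tocoo()
    ainv_i = Kcoo.row.astype(np.int64)
    ainv_j = Kcoo.col.astype(np.int64)
    ainv_val = Kcoo.data.astype(float)

    a_off = n_fixed
    p_off = n_fixed + N_COEF * n_ped
    ap_rows, ap_cols = _expand_block_entries(ainv_i, ainv_j, a_off)
    rec_arange = np.arange(n_rec, dtype=np.int64)
    pp_rows, pp_cols = _expand_block_entries(rec_arange, rec_arange, p_off)

    # union sparsity pattern
    ones = lambda m: sp.csr_matrix(
        (np.ones(m.nnz), m.indices.copy(), m.indptr.copy()), shape=m.shape
    )
    U = ones(Ms[0])
    for Mo in Ms[1:]:
        U = U + ones(Mo)
    U = U + sp.coo_matrix(
        (np.ones(ap_rows.size), (ap_rows, ap_cols)), shape=(ncoef, ncoef)
    ).tocsr()
    U = U + sp.coo_matrix(
        (np.ones(pp_rows.size), (pp_rows, pp_cols)), shape=(ncoef, ncoef)
    ).tocsr()
    U.sum_duplicates()
    U.sort_indices()
    indptr = U.indptr.astype(np.int64)
    indices = U.indices.astype(np.int64)

    def positions(rows, cols):
        out = np.empty(rows.size, dtype=np.int64)
        _gibbs.find_positions(indptr, indices, rows.astype(np.int64),
                              cols.astype(np.int64), out)
        return out

    m_pos_parts, m_val_parts, m_seg = [], [], [0]
    for Mo in Ms:
        coo = Mo.tocoo()
        m_pos_parts.append(positions(coo.row, coo.col))
        m_val_parts.append(coo.data.astype(float))
        m_seg.append(m_seg[-1] + coo.nnz)
    m_pos = np.concatenate(m_pos_parts) if m_pos_parts else np.zeros(0, np.int64)
    m_val = np.concatenate(m_val_parts) if m_val_parts else np.zeros(0)
    m_seg = np.asarray(m_seg, dtype=np.int64)

    ap_pos = positions(ap_rows, ap_cols)
    nnzA = ainv_val.size
    six = np.arange(N_COEF)
    ap_k = np.repeat(np.arange(nnzA, dtype=np.int64), N_COEF * N_COEF)
    ap_r = np.tile(np.repeat(six, N_COEF), nnzA).astype(np.int64)
    ap_c = np.tile(np.tile(six, N_COEF), nnzA).astype(np.int64)

    pp_pos = positions(pp_rows, pp_cols)
    pp_r = np.tile(np.repeat(six, N_COEF), n_rec).astype(np.int64)
    pp_c = np.tile(np.tile(six, N_COEF), n_rec).astype(np.int64)

    if intercept_swap:
        Kdense = np.linalg.inv(K.toarray())
        Kdense = 0.5 * (Kdense + Kdense.T)
        jitter = 0.0
        while True:
            try:
                Lk = np.linalg.cholesky(Kdense + jitter * np.eye(n_ped))
                break
            except np.linalg.LinAlgError:  # pragma: no cover - defensive
                jitter = 1e-8 if jitter == 0 else jitter * 100
    else:
        Lk = np.zeros((0, 0))

    n_keep = chain.n_retained
    out_G = np.zeros((n_keep, N_COEF, N_COEF))
    out_P = np.zeros((n_keep, N_COEF, N_COEF))
    out_s = np.zeros((n_keep, 6))
    theta_mean = np.zeros(ncoef)

    kept = _gibbs.run_chain(
        indptr, indices,
        m_pos, m_val, m_seg, rhs_cls,
        ap_pos, ap_k, ap_r, ap_c, ainv_val, ainv_i, ainv_j,
        pp_pos, pp_r, pp_c,
        W.indptr.astype(np.int64), W.indices.astype(np.int64),
        W.data.astype(float), frame.y.astype(float), rclass,
        n_fixed, n_ped, n_rec,
        np.asarray(priors.S_additive, float), float(priors.df_additive),
        np.asarray(priors.S_pe, float), float(priors.df_pe),
        np.asarray(priors.s_resid, float), float(priors.df_resid),
        Lk,
        K.indptr.astype(np.int64), K.indices.astype(np.int64),
        K.data.astype(float), frame.rec_index.astype(np.int64),
        chain.length, chain.burn_in, chain.thin, int(seed),
        out_G, out_P, out_s, theta_mean,
    )
    if kept != n_keep:  # pragma: no cover - defensive
        raise RuntimeError(f"retained {kept} samples, expected {n_keep}")
    post = PosteriorChain(config=chain, additive=out_G, pe=out_P, resid=out_s)
    sol = SolutionSet.from_theta(theta_mean, frame)
    return post, sol


# --------------------------------------------------------------------------
# convergence diagnostics
# --------------------------------------------------------------------------


def _autocov(x: np.ndarray, max_lag: int) -> np.ndarray:
    n = len(x)
    xc = x - x.mean()
    acov = np.empty(max_lag + 1)
    for k in range(max_lag + 1):
        acov[k] = np.dot(xc[: n - k], xc[k:]) / n
    return acov


def _spectral_var_of_mean(x: np.ndarray) -> float:
    """Variance of the sample mean via the initial positive sequence estimator."""
    n = len(x)
    acov = _autocov(x, min(n - 2, n // 2) if n > 3 else 0)
    if acov[0] <= 0:
        return 0.0
    s = acov[0]
    m = 1
    while m + 1 < len(acov):
        pair = acov[m] + acov[m + 1]
        if pair <= 0:
            break
        s += 2.0 * pair
        m += 2
    return s / n


def geweke_z(x: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score: first 10% vs. last 50% segment means.

    Segment variances use spectral (autocorrelation-consistent) estimates.
    A constant chain returns 0.
    """
    x = np.asarray(x, float)
    if len(x) < 20:
        raise ValueError("chain too short for the Geweke diagnostic")
    a = x[: int(first * len(x))]
    b = x[int((1 - last) * len(x)) :]
    va = _spectral_var_of_mean(a)
    vb = _spectral_var_of_mean(b)
    if va + vb == 0.0:
        return 0.0
    return float((a.mean() - b.mean()) / np.sqrt(va + vb))


def effective_sample_size(x: np.ndarray) -> float:
    """ESS from the autocorrelation sum, truncated at the first negative
    consecutive pair (Geyer's initial positive sequence).

    A zero-variance chain returns n.
    """
    x = np.asarray(x, float)
    n = len(x)
    if n < 4:
        raise ValueError("chain too short for an ESS estimate")
    acov = _autocov(x, min(n - 2, n // 2))
    if acov[0] <= 0:
        return float(n)
    rho = acov / acov[0]
    s = 0.0
    m = 1
    while m + 1 < len(rho):
        pair = rho[m] + rho[m + 1]
        if pair <= 0:
            break
        s += pair
        m += 2
    return float(n / (1.0 + 2.0 * s))


def hpd_interval(x: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``prob`` of the samples."""
    xs = np.sort(np.asarray(x, float))
    n = len(xs)
    k = max(1, int(np.ceil(prob * n)))
    if k >= n:
        return float(xs[0]), float(xs[-1])
    widths = xs[k:] - xs[: n - k]
    i = int(np.argmin(widths))
    return float(xs[i]), float(xs[i + k])
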