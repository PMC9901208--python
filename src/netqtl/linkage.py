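"""Heritability, regression-based multipoint QTL linkage, and
within-region mixed-model association.

The linkage statistic follows the regression-based approach for general
pedigrees: per family, the centered multipoint IBD-sharing estimates
pi_hat of relative pairs are regressed on the squared sums and squared
differences of the (standardized) trait values, with weights derived
from the trait covariance implied by the trait model and from the
sampling covariance of pi_hat.  Family contributions are combined
additively into a score-type chi^2(1) statistic, signed to favour
positive sharing-similarity, and reported as LOD = max(stat, 0) /
(2 ln 10) with negative-direction estimates truncated at zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from netqtl.pedigree import GeneticMap, GenotypeMatrix, IBDProfile, Pedigree, kinship

__all__ = [
    "TraitModel",
    "HeritabilityEstimate",
    "SupportInterval",
    "adjust_covariates",
    "heritability_vc",
    "sham_regression_scan",
    "find_peaks_and_support",
    "lmm_association",
]

LOD_SCALE = 2.0 * np.log(10.0)


# ---------------------------------------------------------------------------
# Covariate adjustment


def adjust_covariates(
    qt: pd.Series, covariates: pd.DataFrame
) -> tuple[pd.Series, pd.Series]:
    """Least-squares residuals of the QT on the covariates (+ intercept).

    Rows with missing covariates are dropped (reported via warning);
    constant covariate columns are dropped with a warning.  Returns
    (residuals indexed by the retained ids, fitted coefficients).
    """
    common = qt.index.intersection(covariates.index)
    cov = covariates.loc[common].apply(pd.to_numeric, errors="coerce")
    y = qt.loc[common].astype(float)
    complete = cov.notna().all(axis=1) & y.notna()
    if (~complete).sum():
        warnings.warn(f"dropping {(~complete).sum()} rows with missing data")
    cov, y = cov.loc[complete], y.loc[complete]
    keep_cols = [c for c in cov.columns if cov[c].nunique() > 1]
    dropped = set(cov.columns) - set(keep_cols)
    if dropped:
        warnings.warn(f"dropping constant covariate columns: {sorted(dropped)}")
    X = np.column_stack([np.ones(len(y))] + [cov[c].to_numpy(float) for c in keep_cols])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn("rank-deficient covariate design; coefficients not unique")
    beta, *_ = np.linalg.lstsq(X, y.to_numpy(), rcond=None)
    resid = y.to_numpy() - X @ beta
    coefs = pd.Series(beta, index=["intercept"] + keep_cols)
    return pd.Series(resid, index=y.index, name=qt.name), coefs


# ---------------------------------------------------------------------------
# Variance-components heritability (REML)


@dataclass
class TraitModel:
    """Population mean, variance and heritability of the adjusted QT —
    the inputs of the regression-based linkage statistic."""

    mean: float
    variance: float
    heritability: float

    def __post_init__(self) -> None:
        if self.variance <= 0:
            raise ValueError("trait variance must be positive")
        if not 0.0 <= self.heritability <= 1.0:
            raise ValueError("heritability must be in [0, 1]")


@dataclass
class HeritabilityEstimate:
    h2: float
    additive_variance: float
    residual_variance: float
    se_h2: float
    loglik: float
    n: int

    def trait_model(self, trait: pd.Series) -> TraitModel:
        return TraitModel(
            mean=float(trait.mean()),
            variance=float(trait.var(ddof=1)),
            heritability=self.h2,
        )


def _block_eigh(K: pd.DataFrame, families: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of a family-block-diagonal kinship matrix,
    computed block by block (exact, much faster than a dense eigh)."""
    ids = list(K.index)
    n = len(ids)
    vals = np.zeros(n)
    vecs = np.zeros((n, n))
    pos = {iid: i for i, iid in enumerate(ids)}
    fam_groups: dict = {}
    for iid in ids:
        fam_groups.setdefault(families.loc[iid], []).append(iid)
    off = 0
    Knp = K.to_numpy(dtype=float)
    for fam, members in fam_groups.items():
        idx = np.array([pos[i] for i in members])
        w, V = np.linalg.eigh(Knp[np.ix_(idx, idx)])
        m = len(idx)
        vals[off:off + m] = w
        vecs[np.ix_(idx, np.arange(off, off + m))] = V
        off += m
    return vals, vecs


def _reml_neg_loglik(h2: float, s: np.ndarray, yr: np.ndarray, Xr: np.ndarray) -> float:
    w = h2 * s + (1.0 - h2)
    if np.any(w <= 0):
        return np.inf
    win = 1.0 / w
    XtWX = (Xr * win[:, None]).T @ Xr
    XtWy = (Xr * win[:, None]).T @ yr
    beta = np.linalg.solve(XtWX, XtWy)
    resid = yr - Xr @ beta
    n, p = Xr.shape
    sigma2 = float(resid @ (win * resid)) / (n - p)
    _, logdet_xwx = np.linalg.slogdet(XtWX)
    return 0.5 * (
        (n - p) * np.log(sigma2) + np.log(w).sum() + logdet_xwx
        + (n - p)
    )


def heritability_vc(
    trait: pd.Series,
    ped: Pedigree,
    covariates: pd.DataFrame | None = None,
) -> HeritabilityEstimate:
    """REML variance-components heritability on a pedigree.

    Fits Omega = 2*Phi*sigma_g^2 + I*sigma_e^2 by eigendecomposition of
    the (family-block) kinship matrix and a bounded one-dimensional
    optimization over h^2 = sigma_g^2 / (sigma_g^2 + sigma_e^2).
    Covariates, if given, enter as fixed effects.
    """
    ids = [i for i in ped.ids if i in trait.index and np.isfinite(trait[i])]
    fam_sizes = ped.table.set_index("id").loc[ids, "family"].value_counts()
    if (fam_sizes >= 2).sum() < 2:
        raise ValueError("need >= 2 families with >= 2 phenotyped relatives")
    K = 2.0 * kinship(ped).loc[ids, ids]
    families = ped.table.set_index("id")["family"].loc[ids]
    s, U = _block_eigh(K, families)
    if s.min() < -1e-8:
        raise ValueError("kinship matrix not positive semidefinite")
    y = trait.loc[ids].to_numpy(dtype=float)
    X = np.ones((len(ids), 1))
    if covariates is not None:
        cc = covariates.loc[ids].apply(pd.to_numeric, errors="coerce")
        cols = [c for c in cc.columns if cc[c].nunique() > 1]
        X = np.column_stack([X] + [cc[c].to_numpy(float) for c in cols])
    yr, Xr = U.T @ y, U.T @ X

    res = optimize.minimize_scalar(
        _reml_neg_loglik, bounds=(0.0, 1.0 - 1e-6), method="bounded",
        args=(s, yr, Xr), options={"xatol": 1e-6},
    )
    h2 = float(res.x)
    # boundary refinement: compare against the endpoints explicitly
    for cand in (0.0, 1.0 - 1e-6):
        if _reml_neg_loglik(cand, s, yr, Xr) < res.fun:
            h2 = cand
    nll = _reml_neg_loglik(h2, s, yr, Xr)
    w = h2 * s + (1.0 - h2)
    win = 1.0 / w
    XtWX = (Xr * win[:, None]).T @ Xr
    beta = np.linalg.solve(XtWX, (Xr * win[:, None]).T @ yr)
    resid = yr - Xr @ beta
    n, p = Xr.shape
    sigma2 = float(resid @ (win * resid)) / (n - p)
    eps = 1e-4
    lo, hi = max(h2 - eps, 0.0), min(h2 + eps, 1.0 - 1e-9)
    d2 = (
        _reml_neg_loglik(lo, s, yr, Xr)
        - 2 * nll
        + _reml_neg_loglik(hi, s, yr, Xr)
    ) / ((hi - lo) / 2) ** 2
    se = float(1.0 / np.sqrt(d2)) if d2 > 0 else float("nan")
    return HeritabilityEstimate(
        h2=h2,
        additive_variance=h2 * sigma2,
        residual_variance=(1.0 - h2) * sigma2,
        se_h2=se,
        loglik=-nll,
        n=len(ids),
    )


# ---------------------------------------------------------------------------
# Regression-based multipoint linkage


def _pair_fourth_moments(r: np.ndarray, pairs: list[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
    """Null mean and covariance of the stacked (squared sums, squared
    differences) vector for standardized multinormal traits with
    correlation matrix r."""
    P = len(pairs)
    mu = np.empty(2 * P)
    for p, (i, j) in enumerate(pairs):
        mu[p] = 2.0 * (1.0 + r[i, j])
        mu[P + p] = 2.0 * (1.0 - r[i, j])
    C = np.empty((2 * P, 2 * P))
    for p, (i, j) in enumerate(pairs):
        for q, (k, l) in enumerate(pairs):
            rik, ril = r[i, k], r[i, l]
            rjk, rjl = r[j, k], r[j, l]
            C[p, q] = 2.0 * (rik + ril + rjk + rjl) ** 2
            C[P + p, P + q] = 2.0 * (rik - ril - rjk + rjl) ** 2
            C[p, P + q] = 2.0 * (rik - ril + rjk - rjl) ** 2
            C[P + p, q] = 2.0 * (rik + ril - rjk - rjl) ** 2
    return mu, C


def _psd_pinv(M: np.ndarray, rcond: float = 1e-10) -> np.ndarray:
    w, V = np.linalg.eigh((M + M.T) / 2.0)
    wmax = max(w.max(), 0.0)
    inv = np.where(w > rcond * max(wmax, 1e-300), 1.0 / np.maximum(w, 1e-300), 0.0)
    return (V * inv) @ V.T


def sham_regression_scan(
    trait: pd.Series,
    ibd: IBDProfile,
    model: TraitModel,
    ped: Pedigree,
    min_expected_pi: float = 0.25,
) -> pd.DataFrame:
    """Genome scan of the regression-based linkage statistic.

    Pairs closer than second degree are excluded by ``min_expected_pi``
    (2*phi >= 0.25 keeps first- and second-degree relatives), as are
    pairs whose IBD sharing carries no linkage information (zero prior
    variance, e.g. parent-offspring).  Returns a frame with columns
    chrom, pos_cm, statistic (signed chi^2(1) scale), lod.
    """
    from netqtl.pedigree import _structure_signature

    y_all = (trait - model.mean) / np.sqrt(model.variance)
    h2 = model.heritability
    kin_cache: dict[tuple, np.ndarray] = {}

    # group families with identical design (same kept pairs & structure)
    groups: dict[tuple, dict] = {}
    for fam in ibd.families:
        pt = ped.family(fam.family)
        sig = _structure_signature(pt)
        if sig not in kin_cache:
            kin_cache[sig] = kinship(pt).to_numpy()
        phi = kin_cache[sig]
        members_ok = {i for i in pt.ids if i in y_all.index and np.isfinite(y_all[i])}
        prior_var = np.diag(fam.prior_cov)
        kept = [
            p
            for p, (a, b) in enumerate(fam.pairs)
            if (
                fam.expected_pi[p] >= min_expected_pi - 1e-9
                and fam.expected_pi[p] < 1.0 - 1e-9
                and prior_var[p] > 1e-9
                and a in members_ok
                and b in members_ok
            )
        ]
        if not kept:
            continue
        idp = {iid: k for k, iid in enumerate(pt.ids)}
        members = sorted({m for p in kept for m in fam.pairs[p]},
                         key=lambda m: idp[m])
        mpos = {m: i for i, m in enumerate(members)}
        pair_idx = [(mpos[fam.pairs[p][0]], mpos[fam.pairs[p][1]]) for p in kept]
        r = np.eye(len(members))
        for i, a in enumerate(members):
            for j, b in enumerate(members):
                if i != j:
                    r[i, j] = 2.0 * phi[idp[a], idp[b]] * h2
        key = (
            fam.chrom,
            tuple(kept),
            tuple(pair_idx),
            tuple(np.round(r[np.triu_indices(len(members), 1)], 10)),
        )
        grp = groups.setdefault(
            key,
            dict(chrom=fam.chrom, pairs=pair_idx, r=r, kept=kept,
                 fams=[], positions=fam.positions),
        )
        yvals = y_all.loc[members].to_numpy(dtype=float)
        grp["fams"].append((fam, yvals))

    if not groups:
        raise ValueError("no informative relative pairs for linkage")

    chrom_pos: dict = {}
    for grp in groups.values():
        chrom_pos.setdefault(grp["chrom"], grp["positions"])

    rows = []
    for chrom, positions in chrom_pos.items():
        T = len(positions)
        num = np.zeros(T)
        den = np.zeros(T)
        for key, grp in groups.items():
            if grp["chrom"] != chrom:
                continue
            pairs = grp["pairs"]
            P = len(pairs)
            mu, C = _pair_fourth_moments(grp["r"], pairs)
            Cinv = _psd_pinv(C)
            kept = list(grp["kept"])
            F = len(grp["fams"])
            Ydev = np.empty((F, 2 * P))
            Pidev = np.empty((F, T, P))
            prior = np.zeros((P, P))
            post_mean = np.zeros((T, P, P))
            for f, (fam, yv) in enumerate(grp["fams"]):
                s = np.array([(yv[i] + yv[j]) ** 2 for i, j in pairs])
                d = np.array([(yv[i] - yv[j]) ** 2 for i, j in pairs])
                Ydev[f] = np.concatenate([s, d]) - mu
                pihat = fam.pihat[:, kept]
                Pidev[f] = pihat - fam.expected_pi[kept][None, :]
                prior += fam.prior_cov[np.ix_(kept, kept)]
                post_mean += fam.post_cov[:, kept, :][:, :, kept]
            prior /= F
            post_mean /= F
            # x_f(t) = W(t) C^-1 (Y_f - mu) with W(t) = 2 [S | -S],
            # S = marginal covariance of pi_hat at t
            CinvY = Ydev @ Cinv  # (F, 2P)
            for t in range(T):
                S = prior - post_mean[t]
                w, V = np.linalg.eigh((S + S.T) / 2.0)
                w = np.clip(w, 0.0, None)
                S = (V * w) @ V.T
                if not np.any(w > 1e-12):
                    continue
                W = 2.0 * np.concatenate([S, -S], axis=1)  # (P, 2P)
                x = CinvY @ W.T  # (F, P)
                A = _psd_pinv(S)
                xA = x @ A
                num[t] += float((xA * Pidev[:, t, :]).sum())
                den[t] += float((xA * x).sum())
        stat = np.where(den > 0, num**2 / np.maximum(den, 1e-300), 0.0)
        signed = np.where(num >= 0, stat, -stat)
        lod = np.where(signed > 0, signed / LOD_SCALE, 0.0)
        for t, pos in enumerate(positions):
            rows.append((chrom, float(pos), float(signed[t]), float(lod[t])))
    scan = pd.DataFrame(rows, columns=["chrom", "pos_cm", "statistic", "lod"])
    return scan.sort_values(["chrom", "pos_cm"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Peaks and support intervals


@dataclass
class SupportInterval:
    chrom: object
    start_cm: float
    end_cm: float
    peak_cm: float
    max_lod: float
    start_marker: str | None = None
    end_marker: str | None = None

    @property
    def length_cm(self) -> float:
        return self.end_cm - self.start_cm


def find_peaks_and_support(
    scan: pd.DataFrame,
    lod_threshold: float = 3.0,
    drop: float = 2.0,
    gmap: GeneticMap | None = None,
) -> list[SupportInterval]:
    """Linkage peaks (LOD > threshold) and their support intervals.

    A support interval is the maximal contiguous run of scan positions
    around a peak with LOD > maxLOD - drop, with endpoints snapped
    outward to the flanking evaluated positions (and annotated with
    flanking marker ids when a map is supplied).
    """
    intervals: list[SupportInterval] = []
    for chrom, sub in scan.groupby("chrom", sort=False):
        sub = sub.sort_values("pos_cm").reset_index(drop=True)
        lod = sub["lod"].to_numpy()
        pos = sub["pos_cm"].to_numpy()
        n = len(lod)
        seen: set[tuple[int, int]] = set()
        for i in range(n):
            left_ok = i == 0 or lod[i] >= lod[i - 1]
            right_ok = i == n - 1 or lod[i] >= lod[i + 1]
            if lod[i] > lod_threshold and left_ok and right_ok:
                cutoff = lod[i] - drop
                lo = i
                while lo > 0 and lod[lo - 1] > cutoff:
                    lo -= 1
                hi = i
                while hi < n - 1 and lod[hi + 1] > cutoff:
                    hi += 1
                lo_snap = max(lo - 1, 0)
                hi_snap = min(hi + 1, n - 1)
                if (lo_snap, hi_snap) in seen:
                    continue
                seen.add((lo_snap, hi_snap))
                iv = SupportInterval(
                    chrom=chrom,
                    start_cm=float(pos[lo_snap]),
                    end_cm=float(pos[hi_snap]),
                    peak_cm=float(pos[i]),
                    max_lod=float(lod[i]),
                )
                if gmap is not None:
                    mk = gmap.chrom_markers(chrom)
                    below = mk.loc[mk["cm"] <= iv.start_cm + 1e-9]
                    above = mk.loc[mk["cm"] >= iv.end_cm - 1e-9]
                    if len(below):
                        iv.start_marker = below["marker"].iloc[-1]
                    if len(above):
                        iv.end_marker = above["marker"].iloc[0]
                intervals.append(iv)
    return intervals


def intervals_to_frame(intervals: list[SupportInterval]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                chrom=iv.chrom, start_cm=iv.start_cm, end_cm=iv.end_cm,
                peak_cm=iv.peak_cm, max_lod=iv.max_lod,
                length_cm=iv.length_cm, start_marker=iv.start_marker,
                end_marker=iv.end_marker,
            )
            for iv in intervals
        ]
    )


# ---------------------------------------------------------------------------
# Kinship LMM association


def _lmm_fit(
    yr: np.ndarray, Xr: np.ndarray, s: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray, float]:
    """Profile-REML fit in the rotated space; returns (h2, beta, cov_beta,
    sigma2)."""
    res = optimize.minimize_scalar(
        _reml_neg_loglik, bounds=(0.0, 1.0 - 1e-6), method="bounded",
        args=(s, yr, Xr), options={"xatol": 1e-6},
    )
    h2 = float(res.x)
    if _reml_neg_loglik(0.0, s, yr, Xr) < res.fun:
        h2 = 0.0
    w = h2 * s + (1.0 - h2)
    win = 1.0 / w
    XtWX = (Xr * win[:, None]).T @ Xr
    beta = np.linalg.solve(XtWX, (Xr * win[:, None]).T @ yr)
    resid = yr - Xr @ beta
    n, p = Xr.shape
    sigma2 = float(resid @ (win * resid)) / (n - p)
    cov_beta = sigma2 * np.linalg.inv(XtWX)
    return h2, beta, cov_beta, sigma2


def lmm_association(
    trait: pd.Series,
    geno: GenotypeMatrix,
    ped: Pedigree,
    markers: list[str] | None = None,
    ref_allele: int = 2,
) -> pd.DataFrame:
    """Single-SNP linear mixed-model association with a kinship random
    effect (exact profile REML via one eigendecomposition of 2*Phi,
    reused across SNPs).

    Returns per-SNP effect, SE, Wald p, the fitted h^2, and the
    per-interval Bonferroni threshold 0.05 / #tested SNPs.
    """
    ids = [i for i in ped.ids if i in trait.index and np.isfinite(trait[i])]
    if len(ids) < 30:
        raise ValueError("need >= 30 phenotyped individuals")
    K = 2.0 * kinship(ped).loc[ids, ids]
    families = ped.table.set_index("id")["family"].loc[ids]
    s, U = _block_eigh(K, families)
    y = trait.loc[ids].to_numpy(dtype=float)
    yr = U.T @ y
    ones_r = U.T @ np.ones(len(ids))
    if markers is None:
        markers = list(geno.gmap.table["marker"])
    rows = []
    skipped = []
    for marker in markers:
        dose = geno.dosage(marker, ref_allele=ref_allele).loc[ids]
        d = dose.to_numpy(dtype=float)
        ok = np.isfinite(d)
        if dose.loc[ok].nunique() < 2:
            skipped.append(marker)
            continue
        if ok.all():
            Xr = np.column_stack([ones_r, U.T @ d])
            h2, beta, cov_beta, _ = _lmm_fit(yr, Xr, s)
        else:
            idx = np.nonzero(ok)[0]
            Ksub = K.iloc[idx, idx]
            ssub, Usub = _block_eigh(Ksub, families.iloc[idx])
            Xs = np.column_stack([np.ones(idx.size), d[idx]])
            h2, beta, cov_beta, _ = _lmm_fit(Usub.T @ y[idx], Usub.T @ Xs, ssub)
        se = float(np.sqrt(cov_beta[1, 1]))
        z = beta[1] / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append(dict(marker=marker, effect=float(beta[1]), se=se,
                         p=float(p), h2=h2))
    out = pd.DataFrame(rows)
    if len(out):
        out["bonferroni_threshold"] = 0.05 / len(out)
        out["significant"] = out["p"] < out["bonferroni_threshold"]
    if skipped:
        out.attrs["skipped_monomorphic"] = skipped
    return out
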