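"""Pedigree representation, kinship coefficients, and multipoint IBD.

Families are modelled as loop-free, non-inbred pedigrees.  Identity-by-
descent sharing along the genome is estimated with a Lander-Green hidden
Markov model over inheritance vectors: one bit per meiosis selects which
parental allele was transmitted, transitions between adjacent markers
follow the Haldane map function, and emissions marginalise over founder
allele assignments consistent with the observed genotypes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Pedigree",
    "GeneticMap",
    "GenotypeMatrix",
    "IBDProfile",
    "FamilyIBD",
    "read_pedigree",
    "read_plink",
    "write_plink",
    "kinship",
    "haldane_theta",
    "multipoint_ibd",
]


# ---------------------------------------------------------------------------
# Pedigree


@dataclass
class Pedigree:
    """Validated pedigree table, topologically sorted (parents first).

    Columns: family, id, father, mother, sex (1=male, 2=female),
    affected (bool).  Founders have father == mother == "0".
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"family", "id", "father", "mother", "sex", "affected"}
        if not required.issubset(t.columns):
            raise ValueError(f"pedigree table needs columns {sorted(required)}")
        t = t.astype({"family": str, "id": str, "father": str, "mother": str})
        if t["id"].duplicated().any():
            dup = t.loc[t["id"].duplicated(), "id"].tolist()
            raise ValueError(f"duplicate individual ids: {dup}")
        known = set(t["id"])
        for col in ("father", "mother"):
            bad = t.loc[(t[col] != "0") & ~t[col].isin(known)]
            if len(bad):
                raise ValueError(f"unknown {col} ids: {bad[col].tolist()}")
        half = t.loc[(t["father"] == "0") != (t["mother"] == "0")]
        if len(half):
            raise ValueError(
                f"individuals with only one parent specified: {half['id'].tolist()}"
            )
        self.table = _toposort(t).reset_index(drop=True)

    @property
    def ids(self) -> list[str]:
        return list(self.table["id"])

    @property
    def founders(self) -> list[str]:
        t = self.table
        return list(t.loc[t["father"] == "0", "id"])

    @property
    def families(self) -> list[str]:
        return list(dict.fromkeys(self.table["family"]))

    @classmethod
    def _validated(cls, table: pd.DataFrame) -> "Pedigree":
        """Construct without re-validation (table already checked/sorted)."""
        obj = object.__new__(cls)
        obj.table = table
        return obj

    def family(self, fam: str) -> "Pedigree":
        if not hasattr(self, "_family_cache"):
            self._family_cache = {
                str(f): Pedigree._validated(sub.reset_index(drop=True))
                for f, sub in self.table.groupby("family", sort=False)
            }
        return self._family_cache[str(fam)]

    def parents(self, iid: str) -> tuple[str, str]:
        row = self.table.loc[self.table["id"] == iid].iloc[0]
        return row["father"], row["mother"]

    def __len__(self) -> int:
        return len(self.table)


def _toposort(t: pd.DataFrame) -> pd.DataFrame:
    """Order individuals so that parents precede offspring; detect loops."""
    idx = {iid: i for i, iid in enumerate(t["id"])}
    order: list[int] = []
    state = np.zeros(len(t), dtype=np.int8)  # 0 unseen, 1 in progress, 2 done
    fathers = t["father"].to_numpy()
    mothers = t["mother"].to_numpy()
    ids = t["id"].to_numpy()

    def visit(i: int, stack: list[int]) -> None:
        if state[i] == 2:
            return
        if state[i] == 1:
            raise ValueError(f"pedigree loop involving individual {ids[i]} "
                             f"(row {i + 1})")
        state[i] = 1
        stack.append(i)
        for p in (fathers[i], mothers[i]):
            if p != "0":
                if p == ids[i]:
                    raise ValueError(
                        f"individual {ids[i]} is its own parent (row {i + 1})"
                    )
                visit(idx[p], stack)
        state[i] = 2
        order.append(i)
        stack.pop()

    for i in range(len(t)):
        visit(i, [])
    return t.iloc[order]


def read_pedigree(path) -> Pedigree:
    """Read a PLINK-style FAM/PED file (first 6 whitespace-delimited columns).

    Columns: family, id, father, mother, sex, phenotype (2 = affected).
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: expected >= 6 columns")
            fam, iid, pat, mat, sex, pheno = parts[:6]
            rows.append(
                dict(family=fam, id=iid, father=pat, mother=mat,
                     sex=int(sex), affected=pheno == "2")
            )
    if not rows:
        raise ValueError(f"{path}: empty pedigree file")
    return Pedigree(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Kinship


def kinship(ped: Pedigree) -> pd.DataFrame:
    """Kinship coefficients phi by the recursive (tabular) method.

    phi(i,i) = 0.5 for non-inbred i; phi(parent, offspring) = 0.25;
    the trait covariance model uses 2*phi (expected proportion of
    alleles shared IBD for non-inbred pairs).
    """
    ids = ped.ids
    n = len(ids)
    pos = {iid: i for i, iid in enumerate(ids)}
    fa = [pos.get(f, -1) for f in ped.table["father"]]
    mo = [pos.get(m, -1) for m in ped.table["mother"]]
    phi = np.zeros((n, n))
    for i in range(n):  # topological order: parents precede offspring
        if fa[i] < 0:
            phi[i, i] = 0.5
        else:
            phi[i, i] = 0.5 + 0.5 * phi[fa[i], mo[i]]
        for j in range(i):
            if fa[i] < 0:
                v = 0.0
            else:
                v = 0.5 * (phi[fa[i], j] + phi[mo[i], j])
            phi[i, j] = phi[j, i] = v
    return pd.DataFrame(phi, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# Genetic map and genotypes


@dataclass
class GeneticMap:
    """Marker map: marker id, chromosome, bp and cM positions."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"marker", "chrom", "bp", "cm"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"genetic map needs columns {sorted(required)}")
        t = self.table
        if t["marker"].duplicated().any():
            raise ValueError("duplicate marker ids in map")
        for chrom, sub in t.groupby("chrom", sort=False):
            cm = sub["cm"].to_numpy(dtype=float)
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"map positions not sorted on chromosome {chrom}")
        self.table = t.reset_index(drop=True)

    @property
    def chroms(self) -> list:
        return list(dict.fromkeys(self.table["chrom"]))

    def chrom_markers(self, chrom) -> pd.DataFrame:
        return self.table.loc[self.table["chrom"] == chrom]

    def marker_index(self) -> dict[str, int]:
        return {m: i for i, m in enumerate(self.table["marker"])}

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GeneticMap":
        return cls(pd.read_csv(path, sep="\t"))

    def write_map(self, path) -> None:
        """PLINK .map format: chrom, marker, cM, bp."""
        self.table[["chrom", "marker", "cm", "bp"]].to_csv(
            path, sep="\t", header=False, index=False
        )

    @classmethod
    def read_map(cls, path) -> "GeneticMap":
        t = pd.read_csv(path, sep=r"\s+", header=None,
                        names=["chrom", "marker", "cm", "bp"])
        return cls(t[["marker", "chrom", "bp", "cm"]])


@dataclass
class GenotypeMatrix:
    """Unphased genotypes: alleles[i, m, :] are the two alleles of
    individual i at marker m (integer codes >= 1; 0 = missing)."""

    ids: list[str]
    gmap: GeneticMap
    alleles: np.ndarray  # (n_ind, n_markers, 2) int

    def __post_init__(self) -> None:
        n, m, two = self.alleles.shape
        if n != len(self.ids) or m != len(self.gmap.table) or two != 2:
            raise ValueError("genotype array shape mismatch")

    def subset_markers(self, markers) -> "GenotypeMatrix":
        midx = self.gmap.marker_index()
        cols = [midx[m] for m in markers]
        sub = self.gmap.table.iloc[cols].reset_index(drop=True)
        return GenotypeMatrix(self.ids, GeneticMap(sub), self.alleles[:, cols, :])

    def dosage(self, marker: str, ref_allele: int = 2) -> pd.Series:
        """Count of ``ref_allele`` copies per individual (missing -> NaN)."""
        m = self.gmap.marker_index()[marker]
        a = self.alleles[:, m, :]
        d = (a == ref_allele).sum(axis=1).astype(float)
        d[(a == 0).any(axis=1)] = np.nan
        return pd.Series(d, index=self.ids)


def write_plink(ped: Pedigree, geno: GenotypeMatrix, ped_path, map_path) -> None:
    """Write pedigree + genotypes as PLINK-style text .ped/.map."""
    geno_by_id = {iid: i for i, iid in enumerate(geno.ids)}
    with open(ped_path, "w") as fh:
        for _, row in ped.table.iterrows():
            fields = [row["family"], row["id"], row["father"], row["mother"],
                      str(int(row["sex"])), "2" if row["affected"] else "1"]
            a = geno.alleles[geno_by_id[row["id"]]].reshape(-1)
            fh.write(" ".join(fields + [str(int(x)) for x in a]) + "\n")
    geno.gmap.write_map(map_path)


def read_plink(ped_path, map_path) -> tuple[Pedigree, GenotypeMatrix]:
    gmap = GeneticMap.read_map(map_path)
    n_markers = len(gmap.table)
    ped = read_pedigree(ped_path)
    rows: dict[str, np.ndarray] = {}
    with open(ped_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            a = np.array(parts[6:], dtype=np.int64)
            if a.size != 2 * n_markers:
                raise ValueError(
                    f"individual {parts[1]}: expected {2 * n_markers} alleles, "
                    f"got {a.size}"
                )
            rows[parts[1]] = a.reshape(n_markers, 2)
    alleles = np.stack([rows[iid] for iid in ped.ids])
    return ped, GenotypeMatrix(ped.ids, gmap, alleles)


def haldane_theta(d_cm: np.ndarray | float):
    """Recombination fraction from Haldane's (no-interference) map function."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


# ---------------------------------------------------------------------------
# Multipoint IBD (Lander-Green)


@dataclass
class FamilyIBD:
    """Per-family multipoint IBD posteriors on one chromosome.

    ``p012[t, p, k]`` is the posterior P(pair p shares k alleles IBD) at
    grid position t; ``post_cov[t]`` the posterior covariance of the pair
    sharing proportions pi given marker data; ``prior_cov`` the covariance
    of pi under the uniform inheritance-vector prior (perfect-information
    variance).  Both feed the weighting of the regression-based linkage
    statistic.
    """

    family: str
    pairs: list[tuple[str, str]]
    expected_pi: np.ndarray  # (P,) = 2*phi per pair
    chrom: object
    positions: np.ndarray  # cM
    p012: np.ndarray  # (T, P, 3)
    post_cov: np.ndarray  # (T, P, P)
    prior_cov: np.ndarray  # (P, P)

    @property
    def pihat(self) -> np.ndarray:
        return self.p012[:, :, 1] * 0.5 + self.p012[:, :, 2]


@dataclass
class IBDProfile:
    """Multipoint IBD sharing for all families, per chromosome."""

    families: list[FamilyIBD] = field(default_factory=list)
    skipped: list[tuple[str, str]] = field(default_factory=list)  # (family, reason)

    def by_chrom(self, chrom) -> list[FamilyIBD]:
        return [f for f in self.families if f.chrom == chrom]

    @property
    def chroms(self) -> list:
        return list(dict.fromkeys(f.chrom for f in self.families))

    def positions(self, chrom) -> np.ndarray:
        fams = self.by_chrom(chrom)
        if not fams:
            raise ValueError(f"no families on chromosome {chrom}")
        return fams[0].positions

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f in self.families:
            pihat = f.pihat
            for p, (a, b) in enumerate(f.pairs):
                for t, pos in enumerate(f.positions):
                    rows.append(
                        (f.family, a, b, f.chrom, pos,
                         f.p012[t, p, 0], f.p012[t, p, 1], f.p012[t, p, 2],
                         pihat[t, p])
                    )
        return pd.DataFrame(
            rows, columns=["family", "id1", "id2", "chrom", "pos_cm",
                           "p0", "p1", "p2", "pi_hat"]
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


class _FamilyHMM:
    """Inheritance-vector machinery for one family.

    The state space enumerates all 2^(2*n_nonfounders) inheritance
    vectors (founder-phase symmetry is not collapsed: at the family
    sizes supported by the bit limit the full space is cheap and keeps
    posteriors directly comparable to brute-force enumeration).
    """

    def __init__(self, fam: Pedigree, max_meioses: int = 10):
        self.ped = fam
        ids = fam.ids
        self.ids = ids
        pos = {iid: i for i, iid in enumerate(ids)}
        t = fam.table
        self.founder = (t["father"] == "0").to_numpy()
        n_nonf = int((~self.founder).sum())
        self.n_meioses = 2 * n_nonf
        if self.n_meioses > max_meioses:
            raise ValueError(
                f"family {t['family'].iloc[0]}: {self.n_meioses} meioses exceed "
                f"the bit limit ({max_meioses})"
            )
        self.n_states = 1 << self.n_meioses
        S = self.n_states
        states = np.arange(S)

        # founder allele slots: founder k gets slots 2k, 2k+1
        self.n_founders = int(self.founder.sum())
        founder_no = np.cumsum(self.founder) - 1
        slots = np.zeros((len(ids), 2, S), dtype=np.int16)
        bit = 0
        fa = [pos.get(f, -1) for f in t["father"]]
        mo = [pos.get(m, -1) for m in t["mother"]]
        for i in range(len(ids)):
            if self.founder[i]:
                slots[i, 0] = 2 * founder_no[i]
                slots[i, 1] = 2 * founder_no[i] + 1
            else:
                bpat = (states >> bit) & 1
                bmat = (states >> (bit + 1)) & 1
                slots[i, 0] = np.take_along_axis(
                    slots[fa[i]], bpat[None, :], axis=0)[0]
                slots[i, 1] = np.take_along_axis(
                    slots[mo[i]], bmat[None, :], axis=0)[0]
                bit += 2
        self.slots = slots  # (n_ind, 2, S)

        # pairwise IBD counts per state for first/second-degree-informative
        # pairs (all distinct pairs kept; callers filter on expected_pi)
        self.pairs: list[tuple[int, int]] = [
            (i, j) for i in range(len(ids)) for j in range(i + 1, len(ids))
        ]
        ibd = np.zeros((len(self.pairs), S), dtype=np.int8)
        for p, (i, j) in enumerate(self.pairs):
            a1, a2 = slots[i, 0], slots[i, 1]
            b1, b2 = slots[j, 0], slots[j, 1]
            ibd[p] = ((a1 == b1) | (a1 == b2)).astype(np.int8) + (
                (a2 == b1) | (a2 == b2)
            ).astype(np.int8)
        self.pair_ibd = ibd

    # -- emission ----------------------------------------------------------

    def emissions(self, alleles: np.ndarray, freqs: list[dict[int, float]]) -> np.ndarray:
        """P(observed genotypes | state) for each marker.

        ``alleles``: (n_ind, n_markers, 2); ``freqs``: per marker a dict
        allele code -> frequency.  Marginalises over founder-slot allele
        assignments by enumerating the phase of each heterozygous
        genotyped individual (injective in the slot assignment for
        non-inbred pedigrees, so no double counting).
        """
        n_ind, n_markers, _ = alleles.shape
        S = self.n_states
        out = np.zeros((n_markers, S))
        n_slots = 2 * self.n_founders
        for m in range(n_markers):
            g = alleles[:, m, :]
            typed = np.nonzero((g > 0).all(axis=1))[0]
            if typed.size == 0:
                out[m] = 1.0
                continue
            het = [i for i in typed if g[i, 0] != g[i, 1]]
            hom = [i for i in typed if g[i, 0] == g[i, 1]]
            C = 1 << len(het)
            combos = np.array(list(itertools.product([0, 1], repeat=len(het))),
                              dtype=np.int8).reshape(C, len(het))
            # allele_of_slot[c, s, state]
            slot_allele = np.full((C, n_slots, S), -1, dtype=np.int32)
            conflict = np.zeros((C, S), dtype=bool)

            def place(ind: int, ordered: np.ndarray) -> None:
                # ordered: (C, 2) alleles for (paternal, maternal) slot
                for k in range(2):
                    sl = self.slots[ind, k]  # (S,)
                    cur = slot_allele[:, sl, np.arange(S)]  # (C, S)
                    new = ordered[:, k][:, None]
                    conflict[:] |= (cur >= 0) & (cur != new)
                    np.put_along_axis(
                        slot_allele, sl[None, None, :].repeat(C, axis=0),
                        np.broadcast_to(new[:, None, :], (C, 1, S)), axis=1)

            for i in hom:
                place(i, np.broadcast_to(g[i, :1], (C, 2)))
            for hidx, i in enumerate(het):
                flip = combos[:, hidx]
                ordered = np.where(flip[:, None] == 0, g[i][None, :],
                                   g[i][::-1][None, :])
                place(i, ordered)

            fr = freqs[m]
            codes = np.array(sorted(fr))
            lut = np.zeros(int(codes.max()) + 2)
            for a in codes:
                lut[a] = fr[a]
            p = np.where(slot_allele < 0, 1.0, lut[np.maximum(slot_allele, 0)])
            p = p.prod(axis=1)  # (C, S)
            p[conflict] = 0.0
            out[m] = p.sum(axis=0)
        return out

    # -- transitions -------------------------------------------------------

    def transition(self, d_cm: float) -> np.ndarray:
        key = (self.n_meioses, round(float(d_cm), 9))
        cached = _TRANSITION_CACHE.get(key)
        if cached is not None:
            return cached
        theta = float(haldane_theta(d_cm))
        flips = self._popcounts()
        m = self.n_meioses
        with np.errstate(divide="ignore"):
            out = theta ** flips * (1.0 - theta) ** (m - flips)
        if len(_TRANSITION_CACHE) < 256:
            _TRANSITION_CACHE[key] = out
        return out

    def _popcounts(self) -> np.ndarray:
        pc = _POPCOUNT_CACHE.get(self.n_meioses)
        if pc is None:
            s = np.arange(self.n_states)
            x = s[:, None] ^ s[None, :]
            pc = np.zeros_like(x)
            while x.any():
                pc += x & 1
                x >>= 1
            _POPCOUNT_CACHE[self.n_meioses] = pc
        return pc


_POPCOUNT_CACHE: dict[int, np.ndarray] = {}
_TRANSITION_CACHE: dict[tuple, np.ndarray] = {}


def _structure_signature(fam: Pedigree) -> tuple:
    """Hashable signature of a family's structure (parent role pattern);
    families with equal signatures share inheritance-vector machinery."""
    t = fam.table
    local = {iid: k for k, iid in enumerate(t["id"])}
    return tuple(
        (local.get(f, -1), local.get(m, -1))
        for f, m in zip(t["father"], t["mother"])
    )


def _forward_backward(em: np.ndarray, trans: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scaled forward/backward over markers. Returns (fwd, bwd, loglik);
    fwd[m] is P(state | data up to m) and bwd[m] the backward message
    normalised to sum 1."""
    M, S = em.shape
    fwd = np.zeros((M, S))
    bwd = np.ones((M, S))
    prior = np.full(S, 1.0 / S)
    a = prior * em[0]
    tot = a.sum()
    if tot == 0:
        raise _MendelError(0)
    loglik = np.log(tot)
    fwd[0] = a / tot
    for m in range(1, M):
        a = (fwd[m - 1] @ trans[m - 1]) * em[m]
        tot = a.sum()
        if tot == 0:
            raise _MendelError(m)
        loglik += np.log(tot)
        fwd[m] = a / tot
    for m in range(M - 2, -1, -1):
        b = trans[m] @ (em[m + 1] * bwd[m + 1])
        tot = b.sum()
        if tot == 0:
            raise _MendelError(m + 1)
        bwd[m] = b / tot
    return fwd, bwd, loglik


class _MendelError(Exception):
    def __init__(self, marker: int):
        self.marker = marker


def _founder_allele_freqs(
    geno: GenotypeMatrix, ped: Pedigree, floor: float = 0.01
) -> list[dict[int, float]]:
    """Allele frequencies counted from founder genotypes, floored.

    The support covers every allele code observed anywhere in the sample
    (codes unseen among founders get the floor frequency), so that a
    missing founder genotype can never zero out an offspring allele.
    """
    founder_set = set(ped.founders)
    fmask = np.array([iid in founder_set for iid in geno.ids])
    out = []
    for m in range(geno.alleles.shape[1]):
        all_a = geno.alleles[:, m, :].reshape(-1)
        support = np.unique(all_a[all_a > 0])
        if support.size == 0:
            out.append({1: 0.5, 2: 0.5})
            continue
        fa = geno.alleles[fmask, m, :].reshape(-1)
        fa = fa[fa > 0]
        if fa.size == 0:
            fa = all_a[all_a > 0]
        counts = np.array([(fa == c).sum() for c in support], dtype=float)
        fr = np.maximum(counts / max(counts.sum(), 1.0), floor)
        fr = fr / fr.sum()
        out.append({int(c): float(f) for c, f in zip(support, fr)})
    return out


def multipoint_ibd(
    ped: Pedigree,
    geno: GenotypeMatrix | None,
    gmap: GeneticMap | None = None,
    grid_cm: float | None = None,
    max_meioses: int = 10,
    allele_freq_floor: float = 0.01,
    on_mendel_error: str = "skip_family",
) -> IBDProfile:
    """Multipoint IBD posteriors for every family at marker positions
    (plus an optional uniform cM grid).

    With ``geno=None`` the posteriors equal the pedigree prior, i.e.
    pihat = 2*phi everywhere.  Mendelian-inconsistent families are either
    skipped (default) or the offending marker is dropped
    (``on_mendel_error='drop_marker'``).
    """
    if gmap is None:
        if geno is None:
            raise ValueError("need a genetic map when no genotypes are given")
        gmap = geno.gmap
    if on_mendel_error not in ("skip_family", "drop_marker"):
        raise ValueError("on_mendel_error must be 'skip_family' or 'drop_marker'")
    freqs_all = (
        _founder_allele_freqs(geno, ped, allele_freq_floor)
        if geno is not None
        else None
    )
    geno_pos = {iid: i for i, iid in enumerate(geno.ids)} if geno is not None else {}
    profile = IBDProfile()
    hmm_cache: dict[tuple, _FamilyHMM] = {}
    for fam_id in ped.families:
        fam = ped.family(fam_id)
        sig = _structure_signature(fam)
        try:
            hmm = hmm_cache.get(sig)
            if hmm is None:
                hmm = _FamilyHMM(fam, max_meioses=max_meioses)
                hmm_cache[sig] = hmm
        except ValueError as exc:
            profile.skipped.append((fam_id, str(exc)))
            continue
        for chrom in gmap.chroms:
            sub = gmap.chrom_markers(chrom)
            marker_cm = sub["cm"].to_numpy(dtype=float)
            marker_rows = sub.index.to_numpy()
            fam_res = _family_chrom_ibd(
                hmm, fam, geno, geno_pos, freqs_all, chrom, marker_cm,
                marker_rows, grid_cm, on_mendel_error,
            )
            if fam_res is None:
                profile.skipped.append(
                    (fam_id, f"Mendelian inconsistency on chromosome {chrom}")
                )
            else:
                profile.families.append(fam_res)
    return profile


def _grid_positions(marker_cm: np.ndarray, grid_cm: float | None) -> np.ndarray:
    pos = list(marker_cm)
    if grid_cm is not None and len(marker_cm) > 0:
        pos += list(np.arange(marker_cm[0], marker_cm[-1] + 1e-9, grid_cm))
    return np.unique(np.asarray(pos, dtype=float))


def _family_chrom_ibd(
    hmm: _FamilyHMM,
    fam: Pedigree,
    geno: GenotypeMatrix | None,
    geno_pos: dict[str, int],
    freqs_all: list[dict[int, float]] | None,
    chrom,
    marker_cm: np.ndarray,
    marker_rows: np.ndarray,
    grid_cm: float | None,
    on_mendel_error: str,
) -> FamilyIBD | None:
    S = hmm.n_states
    ids = fam.ids  # structure matches hmm; ids are family-specific
    n_pairs = len(hmm.pairs)
    if not hasattr(hmm, "_expected_pi"):
        phi = kinship(fam).to_numpy()
        hmm._expected_pi = np.array([2.0 * phi[i, j] for i, j in hmm.pairs])
        hmm._ibd_indicators = np.stack(
            [(hmm.pair_ibd == k).T.astype(float) for k in range(3)]
        )  # (3, S, P)
    expected_pi = hmm._expected_pi
    positions = _grid_positions(marker_cm, grid_cm)
    pair_ibd = hmm.pair_ibd  # (P, S)
    indicators = hmm._ibd_indicators

    def state_moments(w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(p012, cov of pi) under state distribution w."""
        p012 = np.stack([w @ indicators[k] for k in range(3)], axis=1)
        pi_states = pair_ibd * 0.5  # (P, S)
        mean = pi_states @ w
        cov = (pi_states * w) @ pi_states.T - np.outer(mean, mean)
        return p012, cov

    if not hasattr(hmm, "_prior_moments"):
        uniform = np.full(S, 1.0 / S)
        hmm._prior_moments = state_moments(uniform)
    prior_p012, prior_cov = hmm._prior_moments

    if geno is None or len(marker_cm) == 0:
        T = len(positions)
        return FamilyIBD(
            family=fam.table["family"].iloc[0],
            pairs=[(ids[i], ids[j]) for i, j in hmm.pairs],
            expected_pi=expected_pi,
            chrom=chrom,
            positions=positions,
            p012=np.broadcast_to(prior_p012, (T, n_pairs, 3)).copy(),
            post_cov=np.broadcast_to(prior_cov, (T, n_pairs, n_pairs)).copy(),
            prior_cov=prior_cov,
        )

    rows = [geno_pos[iid] for iid in ids]
    alleles = geno.alleles[rows][:, marker_rows, :]
    freqs = [freqs_all[r] for r in marker_rows]
    cm = marker_cm.copy()

    while True:
        em = hmm.emissions(alleles, freqs)
        trans = [hmm.transition(cm[m + 1] - cm[m]) for m in range(len(cm) - 1)]
        try:
            fwd, bwd, _ = _forward_backward(em, trans)
            break
        except _MendelError as exc:
            if on_mendel_error == "skip_family":
                return None
            keep = np.ones(len(cm), dtype=bool)
            keep[exc.marker] = False
            alleles = alleles[:, keep, :]
            freqs = [f for f, k in zip(freqs, keep) if k]
            cm = cm[keep]
            if len(cm) == 0:
                return None

    T = len(positions)
    p012 = np.zeros((T, n_pairs, 3))
    post_cov = np.zeros((T, n_pairs, n_pairs))
    for t, pos in enumerate(positions):
        w = _posterior_at(pos, cm, fwd, bwd, em, hmm)
        p012[t], post_cov[t] = state_moments(w)
    return FamilyIBD(
        family=fam.table["family"].iloc[0],
        pairs=[(ids[i], ids[j]) for i, j in hmm.pairs],
        expected_pi=expected_pi,
        chrom=chrom,
        positions=positions,
        p012=p012,
        post_cov=post_cov,
        prior_cov=prior_cov,
    )


def _posterior_at(
    pos: float,
    cm: np.ndarray,
    fwd: np.ndarray,
    bwd: np.ndarray,
    em: np.ndarray,
    hmm: _FamilyHMM,
) -> np.ndarray:
    """Exact HMM posterior over states at an arbitrary map position."""
    M = len(cm)
    left = int(np.searchsorted(cm, pos, side="right")) - 1
    if left >= 0 and np.isclose(cm[left], pos):
        w = fwd[left] * bwd[left]
        return w / w.sum()
    if left < 0:  # before the first marker
        w = (em[0] * bwd[0]) @ hmm.transition(cm[0] - pos).T
        w /= hmm.n_states
        return w / w.sum()
    if left >= M - 1:  # beyond the last marker
        w = fwd[M - 1] @ hmm.transition(pos - cm[M - 1])
        return w / w.sum()
    a = fwd[left] @ hmm.transition(pos - cm[left])
    b = hmm.transition(cm[left + 1] - pos) @ (em[left + 1] * bwd[left + 1])
    w = a * b
    return w / w.sum()
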