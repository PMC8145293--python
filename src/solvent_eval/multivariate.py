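"""Ordination and community-level inference on LC-MS feature profiles.

The workflow follows standard ecological multivariate practice: square-root
transform of abundances, Bray-Curtis dissimilarity, principal coordinate
analysis, and distance-based multi-factor PERMANOVA (McArdle-Anderson
partition of the Gower-centred matrix) with pseudo-F significance assessed by
Freedman-Lane permutation of residuals under the reduced model.

The PERMANOVA engine targets balanced crossed designs with an optional random
replicate factor nested in one of the fixed factors (the two bioreactor
designs in scope: solvent x stage, and solvent x stage x compartment, with
replicates nested in stage).  Sums of squares are sequential, which for these
balanced designs is an orthogonal partition: term SS plus residual SS equals
total SS.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .core_io import FeatureTable, SampleMetadata


@dataclass
class DesignSpec:
    """Model terms for the PERMANOVA partition.

    ``fixed_terms`` are tuples of metadata factor names; a single name is a
    main effect, several names an interaction (e.g. ``("solvent", "stage")``).
    ``random_nested`` optionally declares a random factor nested within a
    fixed factor, e.g. ``("replicate", "stage")`` for technical replicates
    nested in experimental stage.  Tests of terms not involving the nesting
    parent permute within its levels (exchangeability blocks); other terms
    permute freely.
    """

    fixed_terms: list[tuple[str, ...]]
    random_nested: tuple[str, str] | None = None

    def all_factors(self) -> set[str]:
        out = set()
        for t in self.fixed_terms:
            out.update(t)
        if self.random_nested:
            out.update(self.random_nested)
        return out


def reactor_a_design() -> DesignSpec:
    """Solvent x stage crossed fixed factors, replicates nested in stage."""
    return DesignSpec(
        fixed_terms=[("solvent",), ("stage",), ("solvent", "stage")],
        random_nested=("replicate", "stage"),
    )


def reactor_b_design() -> DesignSpec:
    """Solvent x stage x compartment crossed fixed factors, replicates
    nested in stage."""
    return DesignSpec(
        fixed_terms=[
            ("solvent",),
            ("compartment",),
            ("stage",),
            ("solvent", "compartment"),
            ("solvent", "stage"),
            ("compartment", "stage"),
            ("solvent", "compartment", "stage"),
        ],
        random_nested=("replicate", "stage"),
    )


# ---------------------------------------------------------------------------
# distances and ordination
# ---------------------------------------------------------------------------

def bray_curtis(table: FeatureTable, transform: str = "sqrt") -> DistanceMatrix:
    """Bray-Curtis dissimilarities between samples of a feature table.

    Intensities are element-wise transformed first (``sqrt`` by default,
    ``none`` for raw abundances).  A pair of all-zero samples has distance 0.
    """
    x = table.intensities.to_numpy(float).T  # samples x features
    if np.any(x < 0):
        raise ValueError("negative intensities")
    if x.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if transform == "sqrt":
        x = np.sqrt(x)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    d = pdist(x, metric="braycurtis")
    d = np.nan_to_num(d, nan=0.0)  # all-zero pairs
    return DistanceMatrix(squareform(d), ids=table.sample_ids)


@dataclass
class PcoaResult:
    coordinates: pd.DataFrame  # samples x positive axes
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives reported)
    proportion_explained: np.ndarray  # per positive axis, of the positive sum


def gower_center(d_squared: np.ndarray) -> np.ndarray:
    """Gower-centred inner-product matrix B = -1/2 J D2 J."""
    n = d_squared.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ d_squared @ j


def pcoa(distance: DistanceMatrix) -> PcoaResult:
    """Classical principal coordinate analysis.

    Eigendecomposition of the Gower-centred matrix; coordinates are
    eigenvectors scaled by the square root of their (positive) eigenvalues.
    Negative eigenvalues, which arise for semi-metric dissimilarities such as
    Bray-Curtis, are reported unchanged with no correction applied.
    """
    d = np.asarray(distance.data, dtype=float)
    b = gower_center(d**2)
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # zero-out numerically-zero eigenvalues relative to the largest magnitude
    tol = 1e-12 * max(1.0, np.abs(evals).max())
    pos = evals > tol
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    axes = [f"PC{i + 1}" for i in range(int(pos.sum()))]
    prop = evals[pos] / evals[pos].sum() if pos.any() else np.array([])
    return PcoaResult(
        coordinates=pd.DataFrame(coords, index=list(distance.ids), columns=axes),
        eigenvalues=evals,
        proportion_explained=prop,
    )


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _column_space_projector(x: np.ndarray) -> np.ndarray:
    """Orthogonal projector onto the column space of x."""
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    rank = int((s > 1e-10 * max(1.0, s.max())).sum())
    u = u[:, :rank]
    return u @ u.T


def _cell_indicators(meta: pd.DataFrame, factors: tuple[str, ...]) -> np.ndarray:
    labels = meta[list(factors)].astype(str).agg("|".join, axis=1)
    return pd.get_dummies(labels, dtype=float).to_numpy()


def _check_balanced(meta: pd.DataFrame, factors: list[str]) -> None:
    if not factors:
        return
    counts = meta.groupby([meta[f].astype(str) for f in factors], observed=True).size()
    if counts.nunique() != 1:
        raise ValueError(
            "unbalanced design: unequal replication across cells of "
            + " x ".join(factors)
        )


@dataclass
class PermanovaTable:
    table: pd.DataFrame  # term, df, ss, ms, pseudo_f, p_value (+p_mc for posthoc)
    n_permutations: int | str
    seed: int | None = None
    extras: dict = field(default_factory=dict)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.table.to_string(index=False)


def _term_projectors(meta: pd.DataFrame, design: DesignSpec):
    """Sequential orthogonal projectors for each model term.

    Terms enter in the declared fixed order, random nested term last; each
    term's projector is the increment of the cumulative column-space
    projector, so on balanced designs the projectors are mutually orthogonal
    and the SS partition is exact.
    """
    n = len(meta)
    terms: list[tuple[str, tuple[str, ...]]] = []
    for t in design.fixed_terms:
        terms.append((" x ".join(t), t))
    if design.random_nested:
        child, parent = design.random_nested
        terms.append((f"{child}({parent})", (parent, child)))
    x = np.ones((n, 1))
    p_prev = _column_space_projector(x)
    out = []
    for name, factors in terms:
        x = np.hstack([x, _cell_indicators(meta, factors)])
        p_cur = _column_space_projector(x)
        h = p_cur - p_prev
        df = int(round(np.trace(h)))
        if df < 1:
            raise ValueError(f"term {name} has zero degrees of freedom")
        out.append((name, factors, h, df))
        p_prev = p_cur
    return out, p_prev  # p_prev is the full-model projector


def _permutation_blocks(meta: pd.DataFrame, design: DesignSpec, factors: tuple[str, ...]):
    """Indices of exchangeable sample blocks for a test of ``factors``."""
    if design.random_nested:
        _, parent = design.random_nested
        if parent not in factors:
            labels = meta[parent].astype(str)
            return [np.flatnonzero(labels.to_numpy() == lev) for lev in labels.unique()]
    return [np.arange(len(meta))]


def _block_permutation(rng: np.random.Generator, blocks, n: int) -> np.ndarray:
    perm = np.arange(n)
    for b in blocks:
        perm[b] = rng.permutation(perm[b])
    return perm


def _iter_block_permutations(blocks, n: int):
    """All permutations respecting blocks (exhaustive enumeration)."""
    per_block = [list(itertools.permutations(b)) for b in blocks]
    for combo in itertools.product(*per_block):
        perm = np.arange(n)
        for b, p in zip(blocks, combo):
            perm[b] = p
        yield perm


def permanova(
    distance: DistanceMatrix,
    metadata: SampleMetadata | pd.DataFrame,
    design: DesignSpec,
    n_perm: int | str = 9999,
    seed: int | None = None,
    test_terms=None,
    scheme: str = "residual-basis",
) -> PermanovaTable:
    """Multi-factor PERMANOVA on a distance matrix.

    Partitions the total sum of squares (sum of squared distances / n) among
    the declared terms via traces of term projectors against the
    Gower-centred matrix.  Each fixed term's pseudo-F uses the residual mean
    square remaining after the random nested replicate term is removed.

    P-values come from permutation of reduced-model residuals.  The default
    ``scheme="residual-basis"`` permutes the residuals expressed in an
    orthonormal basis of the reduced model's orthocomplement, where the
    coordinates are exchangeable (sample-level residuals of a rank-deficient
    fit are correlated, and permuting them directly gives a noticeably
    conservative test on balanced designs).  ``scheme="sample"`` is the
    classic sample-level Freedman-Lane variant, applying
    M = H_r + P (I - H_r) to the Gower matrix with exchangeability blocks
    that respect the nested replicate structure; it is also used for
    ``n_perm="exhaustive"``, where every blockwise permutation is enumerated
    and the p-value is the exact proportion of permutations (identity
    included) with F* >= F (for a one-factor design this coincides with
    label enumeration).  ``test_terms`` optionally restricts permutation
    testing to the named terms (others report NaN p-values); SS/DF are
    always reported.
    """
    meta = metadata.table if isinstance(metadata, SampleMetadata) else metadata
    ids = list(distance.ids)
    meta = meta.loc[ids]
    factors = sorted(design.all_factors())
    missing = [f for f in factors if f not in meta.columns]
    if missing:
        raise ValueError(f"design references undeclared metadata factor(s) {missing}")
    crossed = sorted({f for t in design.fixed_terms for f in t})
    _check_balanced(meta, crossed)
    for t in design.fixed_terms:
        for f in t:
            if meta[f].astype(str).nunique() < 2:
                raise ValueError(f"factor {f!r} has fewer than 2 levels")

    n = len(ids)
    d = np.asarray(distance.data, dtype=float)
    g = gower_center(d**2)
    ss_total = float(np.trace(g))

    terms, h_full = _term_projectors(meta, design)
    i_n = np.eye(n)
    r_full = i_n - h_full
    df_res = n - int(round(np.trace(h_full)))
    if df_res < 1:
        raise ValueError("saturated model: no residual degrees of freedom")
    ss_res = float(np.sum(r_full * g.T))
    ms_res = ss_res / df_res

    rng = np.random.default_rng(seed)
    rows = []
    for name, tfactors, h_t, df_t in terms:
        ss_t = float(np.sum(h_t * g.T))
        ms_t = ss_t / df_t
        f_obs = ms_t / ms_res
        is_random = design.random_nested and name.startswith(design.random_nested[0])
        if is_random or (test_terms is not None and name not in test_terms):
            rows.append((name, df_t, ss_t, ms_t, f_obs, np.nan))
            continue
        h_red = h_full - h_t

        if n_perm == "exhaustive" or scheme == "sample":
            r_red = i_n - h_red
            blocks = _permutation_blocks(meta, design, tfactors)

            def f_for(perm):
                m = h_red + r_red[perm]  # rows of (I - H_red) permuted
                g_star = m @ g @ m.T
                ss_t_s = float(np.sum(h_t * g_star.T))
                ss_r_s = float(np.sum(r_full * g_star.T))
                return (ss_t_s / df_t) / max(ss_r_s / df_res, 1e-300)

            if n_perm == "exhaustive":
                fs = np.array([f_for(p) for p in _iter_block_permutations(blocks, n)])
                p_val = float(np.mean(fs >= f_obs - 1e-12))
            else:
                count = 0
                for _ in range(int(n_perm)):
                    perm = _block_permutation(rng, blocks, n)
                    if f_for(perm) >= f_obs - 1e-12:
                        count += 1
                p_val = (count + 1) / (int(n_perm) + 1)
        elif scheme == "residual-basis":
            # orthonormal basis V of the reduced model's orthocomplement:
            # the tested-term space plus the residual space, with
            # exchangeable coordinates under the null
            evals, evecs = np.linalg.eigh(i_n - h_red)
            v = evecs[:, evals > 0.5]
            b = v.T @ g @ v
            h_t_r = v.T @ h_t @ v
            r_full_r = v.T @ r_full @ v
            q = b.shape[0]
            count = 0
            for _ in range(int(n_perm)):
                perm = rng.permutation(q)
                b_p = b[np.ix_(perm, perm)]
                ss_t_s = float(np.sum(h_t_r * b_p.T))
                ss_r_s = float(np.sum(r_full_r * b_p.T))
                f_s = (ss_t_s / df_t) / max(ss_r_s / df_res, 1e-300)
                if f_s >= f_obs - 1e-12:
                    count += 1
            p_val = (count + 1) / (int(n_perm) + 1)
        else:
            raise ValueError(f"unknown permutation scheme {scheme!r}")
        rows.append((name, df_t, ss_t, ms_t, f_obs, p_val))

    rows.append(("Residuals", df_res, ss_res, ms_res, np.nan, np.nan))
    table = pd.DataFrame(rows, columns=["term", "df", "ss", "ms", "pseudo_f", "p_value"])
    return PermanovaTable(table=table, n_permutations=n_perm, seed=seed,
                          extras={"ss_total": ss_total})


def pairwise_posthoc(
    distance: DistanceMatrix,
    metadata: SampleMetadata | pd.DataFrame,
    factor: str,
    within: str | None = None,
    n_perm: int = 9999,
    seed: int | None = None,
    mc_threshold: int = 100,
) -> pd.DataFrame:
    """Pairwise comparisons between levels of ``factor``.

    Each pair is tested with a two-level one-factor PERMANOVA restricted to
    the pair's samples (optionally within each level of a conditioning
    factor); pseudo-t is the square root of pseudo-F.  When the number of
    distinct label rearrangements is below ``mc_threshold`` the permutation
    p is supplemented by a Monte-Carlo p from a gamma fit (method of moments)
    to the permuted pseudo-F sample.
    """
    meta = metadata.table if isinstance(metadata, SampleMetadata) else metadata
    ids = list(distance.ids)
    meta = meta.loc[ids]
    rng = np.random.default_rng(seed)
    strata = [(None, meta)] if within is None else [
        (lev, meta[meta[within].astype(str) == str(lev)])
        for lev in meta[within].astype(str).unique()
    ]
    rows = []
    for stratum, sub in strata:
        levels = list(pd.unique(sub[factor].astype(str)))
        for a, b in itertools.combinations(levels, 2):
            sel = sub[sub[factor].astype(str).isin([a, b])]
            n1 = int((sel[factor].astype(str) == a).sum())
            n2 = len(sel) - n1
            if n1 < 2 or n2 < 2:
                continue  # skipped: too few samples to test
            dsub = distance.filter(list(sel.index))
            spec = DesignSpec(fixed_terms=[(factor,)])
            res = permanova(dsub, sel, spec, n_perm=n_perm,
                            seed=int(rng.integers(2**31 - 1)))
            f_obs = float(res.table.loc[res.table["term"] == factor, "pseudo_f"].iloc[0])
            p_perm = float(res.table.loc[res.table["term"] == factor, "p_value"].iloc[0])
            n_distinct = math.comb(n1 + n2, n1)
            p_mc = np.nan
            if n_distinct < mc_threshold:
                fs = _null_f_sample(dsub, sel, factor, 999,
                                    np.random.default_rng(rng.integers(2**31 - 1)))
                mean, var = fs.mean(), fs.var()
                if var > 0 and mean > 0:
                    shape = mean**2 / var
                    scale = var / mean
                    p_mc = float(stats.gamma.sf(f_obs, a=shape, scale=scale))
            rows.append(
                {
                    "within": stratum,
                    "level_a": a,
                    "level_b": b,
                    "pseudo_t": math.sqrt(max(f_obs, 0.0)),
                    "p_perm": p_perm,
                    "n_distinct_perms": n_distinct,
                    "p_mc": p_mc,
                }
            )
    return pd.DataFrame(rows)


def _null_f_sample(distance, meta, factor, n_draws, rng) -> np.ndarray:
    """Sample the permutation distribution of one-factor pseudo-F."""
    spec = DesignSpec(fixed_terms=[(factor,)])
    n = len(meta)
    g = gower_center(np.asarray(distance.data, float) ** 2)
    terms, h_full = _term_projectors(meta, spec)
    _, _, h_t, df_t = terms[0]
    r_full = np.eye(n) - h_full
    df_res = n - int(round(np.trace(h_full)))
    fs = np.empty(n_draws)
    for i in range(n_draws):
        perm = rng.permutation(n)
        g_star = g[np.ix_(perm, perm)]
        ss_t = float(np.sum(h_t * g_star.T))
        ss_r = float(np.sum(r_full * g_star.T))
        fs[i] = (ss_t / df_t) / max(ss_r / df_res, 1e-300)
    return fs
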