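"""16S downstream statistics.

Alpha diversity (bias-corrected Chao1, Shannon entropy, Gini-Simpson),
Bray-Curtis beta diversity with PCoA ordination, Kruskal-Wallis and
PERMANOVA tests, TMM (trimmed mean of M-values) normalization, and a
negative-binomial GLM Wald test of differential abundance with
Benjamini-Hochberg FDR, plus the study's standard set of group contrasts.

Diversity indices, ordination, and the permutation test are delegated to
scikit-bio/scipy; TMM and the NB-Wald chain are implemented here. Samples
are rarefied (seeded subsampling without replacement) to a fixed depth
before diversity estimation, but never before differential abundance -
TMM and the library-size offset handle depth there.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from scipy.optimize import minimize_scalar
from scipy.stats import rankdata
from skbio.diversity import beta_diversity
from skbio.diversity.alpha import chao1 as _skbio_chao1
from skbio.diversity.alpha import shannon as _skbio_shannon
from skbio.diversity.alpha import simpson as _skbio_simpson
from skbio.stats.distance import DistanceMatrix
from skbio.stats.distance import permanova as _skbio_permanova
from skbio.stats.ordination import pcoa as _skbio_pcoa
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .simulate import OTUTable

log = logging.getLogger(__name__)

RAREFACTION_DEPTH = 10_000
_DISPERSION_FLOOR = 1e-8


class MicrobiomeError(ValueError):
    pass


# ---------------------------------------------------------------- diversity

def chao1_bc(counts) -> float:
    """Bias-corrected Chao1 richness: S_obs + f1*(f1-1) / (2*(f2+1))."""
    c = np.asarray(counts)
    if c.sum() == 0:
        raise MicrobiomeError("empty sample: no reads")
    return float(_skbio_chao1(c, bias_corrected=True))


def shannon(counts, base: float = math.e) -> float:
    """Shannon entropy, natural log by default (``base=2`` for bits)."""
    return float(_skbio_shannon(np.asarray(counts), base=base))


def simpson(counts, gini: bool = True) -> float:
    """Simpson's index: Gini-Simpson ``1 - sum p_i^2`` by default, the raw
    dominance ``sum p_i^2`` with ``gini=False``."""
    d = float(_skbio_simpson(np.asarray(counts)))
    return d if gini else 1.0 - d


def rarefy(table: OTUTable, depth: int = RAREFACTION_DEPTH,
           seed: int | np.random.Generator = 0) -> OTUTable:
    """Subsample every sample to ``depth`` reads without replacement.

    Samples with fewer reads than ``depth`` are dropped with a warning,
    matching the practice of excluding under-sequenced samples before
    diversity comparison.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    keep = {}
    dropped = []
    for s in table.counts.columns:
        col = table.counts[s].to_numpy(dtype=np.int64)
        if col.sum() < depth:
            dropped.append(s)
            continue
        keep[s] = rng.multivariate_hypergeometric(col, depth)
    if dropped:
        log.warning("rarefy: dropped %d sample(s) below %d reads: %s",
                    len(dropped), depth, dropped[:6])
    if not keep:
        raise MicrobiomeError(f"no sample reaches the rarefaction depth "
                              f"{depth}")
    return OTUTable(counts=pd.DataFrame(keep, index=table.counts.index),
                    taxonomy=table.taxonomy)


def alpha_diversity_table(table: OTUTable) -> pd.DataFrame:
    """Per-sample Chao1 (bias-corrected), Shannon, and Gini-Simpson."""
    rows = {}
    for s in table.counts.columns:
        c = table.counts[s].to_numpy()
        rows[s] = {"chao1_bc": chao1_bc(c), "shannon": shannon(c),
                   "simpson": simpson(c)}
    return pd.DataFrame(rows).T


def bray_curtis(table_or_matrix, ids=None) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between samples.

    Accepts an :class:`OTUTable` (columns = samples) or a samples x taxa
    matrix.
    """
    if isinstance(table_or_matrix, OTUTable):
        mat = table_or_matrix.counts.T.to_numpy(dtype=float)
        ids = list(table_or_matrix.counts.columns)
    else:
        mat = np.asarray(table_or_matrix, dtype=float)
        if ids is None:
            ids = [str(i) for i in range(mat.shape[0])]
    return beta_diversity("braycurtis", mat, ids=list(ids))


def pcoa(distances: DistanceMatrix, k: int | None = None
         ) -> tuple[pd.DataFrame, pd.Series]:
    """Principal coordinates of a distance matrix.

    Gower double-centering + eigendecomposition; axes with non-positive
    eigenvalues are dropped (with a warning when negative eigenvalues are
    present). Returns ``(coordinates, eigenvalues)`` for the retained
    axes, eigenvalues descending.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = _skbio_pcoa(distances, method="eigh")
    eig = res.eigvals
    if (eig < -1e-8 * max(float(eig.max()), 1.0)).any():
        log.warning("pcoa: negative eigenvalues present (non-Euclidean "
                    "distances); their axes are dropped")
    pos = eig[eig > 1e-12]
    coords = res.samples[pos.index]
    if k is not None:
        pos = pos.iloc[:k]
        coords = coords[pos.index]
    return coords, pos


def permanova(distances: DistanceMatrix, groups, n_perm: int = 999,
              seed: int = 0) -> tuple[float, float]:
    """PERMANOVA pseudo-F and permutation p-value.

    ``p = (1 + #{permuted F >= observed}) / (1 + n_perm)``, label
    permutations seeded.
    """
    res = _skbio_permanova(distances, list(groups), permutations=n_perm,
                           seed=seed)
    return float(res["test statistic"]), float(res["p-value"])


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Kruskal-Wallis rank test with tie correction (chi-square p)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    samples = [values[groups == g] for g in pd.unique(groups)]
    if len(samples) < 2:
        raise MicrobiomeError("Kruskal-Wallis needs >= 2 groups")
    if np.all(values == values[0]):
        return 0.0, 1.0  # fully tied data: no evidence by convention
    h, p = scipy.stats.kruskal(*samples)
    return float(h), float(p)


# ---------------------------------------------------------------------- TMM

def _tmm_pair_factor(obs: np.ndarray, ref: np.ndarray,
                     logratio_trim: float = 0.30,
                     sum_trim: float = 0.05) -> float:
    """TMM factor of one sample against the reference.

    Weighted mean of trimmed log2 ratios (M-values), 30% two-sided trim on
    M and 5% on A (average log abundance), weights the inverse asymptotic
    (delta-method) variances; taxa with a zero in either sample are
    excluded before trimming.
    """
    n_obs, n_ref = obs.sum(), ref.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        logr = np.log2((obs / n_obs) / (ref / n_ref))
        abs_e = (np.log2(obs / n_obs) + np.log2(ref / n_ref)) / 2.0
        v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    fin = np.isfinite(logr) & np.isfinite(abs_e)
    logr, abs_e, v = logr[fin], abs_e[fin], v[fin]
    if logr.size == 0 or np.max(np.abs(logr)) < 1e-6:
        return 1.0
    n = logr.size
    lo_l = math.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = math.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rl = rankdata(logr)
    rs = rankdata(abs_e)
    keep = (rl >= lo_l) & (rl <= hi_l) & (rs >= lo_s) & (rs <= hi_s)
    if not keep.any():
        return 1.0
    f = np.sum(logr[keep] / v[keep]) / np.sum(1.0 / v[keep])
    return float(2.0 ** f)


def tmm_factors(table: OTUTable, reference: str | None = None) -> pd.Series:
    """Per-sample TMM normalization factors, geometric mean 1.

    The reference defaults to the sample whose upper-quartile proportion
    is closest to the mean upper quartile across samples.
    """
    counts = table.counts.to_numpy(dtype=float)
    samples = list(table.counts.columns)
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        bad = [s for s, l in zip(samples, lib) if l == 0]
        raise MicrobiomeError(f"sample(s) with all-zero counts: {bad}")
    if reference is None:
        uq = np.array([np.quantile(counts[:, i] / lib[i], 0.75)
                       for i in range(len(samples))])
        ref_i = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        if reference not in samples:
            raise MicrobiomeError(f"unknown reference sample {reference!r}")
        ref_i = samples.index(reference)
    ref = counts[:, ref_i]
    f = np.array([_tmm_pair_factor(counts[:, i], ref)
                  for i in range(len(samples))])
    f /= np.exp(np.mean(np.log(f)))  # renormalize to geometric mean 1
    return pd.Series(f, index=samples, name="tmm_factor")


# --------------------------------------------------------------------- DAA

@dataclass
class DAAResult:
    """Per-taxon differential abundance between two groups."""

    table: pd.DataFrame  # max_group_mean, log2_fold_change, fold_change,
    #                      wald_p, fdr_p
    group_pair: tuple[str, str]
    excluded: list[str]  # taxa all-zero in both groups


def fold_change(log2fc: float) -> float:
    """Fold change ``2**log2fc`` rounded to 2 significant figures."""
    fc = 2.0 ** float(log2fc)
    if fc == 0:
        return 0.0
    exp = math.floor(math.log10(abs(fc)))
    return round(fc, -exp + 1)


def _nb_wald_one(y: np.ndarray, x: np.ndarray, offset: np.ndarray
                 ) -> tuple[float, float]:
    """NB GLM Wald test for one taxon: returns (beta, p).

    The per-taxon dispersion is profiled by maximum likelihood (floored at
    1e-8); beta is the group coefficient on the natural-log scale.
    """
    X = sm.add_constant(x)

    def fit(alpha):
        fam = sm.families.NegativeBinomial(alpha=alpha)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return sm.GLM(y, X, family=fam, offset=offset).fit(maxiter=100)

    def nll(log_alpha):
        try:
            return -fit(math.exp(log_alpha)).llf
        except Exception:
            return np.inf

    opt = minimize_scalar(nll, bounds=(math.log(_DISPERSION_FLOOR),
                                       math.log(1e3)),
                          method="bounded", options={"xatol": 1e-3})
    alpha = (math.exp(opt.x) if np.isfinite(opt.fun)
             else _DISPERSION_FLOOR)
    try:
        res = fit(alpha)
    except Exception:
        return np.nan, np.nan
    beta = float(res.params[1])
    se = float(res.bse[1])
    if not np.isfinite(se) or se == 0:
        return beta, np.nan
    z = beta / se
    return beta, float(2.0 * scipy.stats.norm.sf(abs(z)))


def daa_wald(table: OTUTable, design: pd.DataFrame,
             group_pair: tuple[str, str],
             factors: pd.Series | None = None,
             group_column: str = "group") -> DAAResult:
    """Wald differential abundance between two sample groups.

    Negative-binomial GLM per taxon with log link and offset
    ``log(library_size * TMM factor)``; the Wald p-value tests the
    ``group_pair[1]`` vs ``group_pair[0]`` coefficient, reported as a
    log2 fold change. BH FDR is applied across the tested taxa. Taxa with
    zero counts in both groups are excluded and logged.
    """
    g1, g2 = group_pair
    meta = design.set_index("sample_id").reindex(table.counts.columns)
    mask = meta[group_column].isin([g1, g2])
    if mask.sum() != len(meta):
        table = OTUTable(counts=table.counts.loc[:, mask.to_numpy()],
                         taxonomy=table.taxonomy)
        meta = meta[mask]
    for g in (g1, g2):
        if (meta[group_column] == g).sum() < 2:
            raise MicrobiomeError(f"group {g!r} has fewer than 2 samples")
    if factors is None:
        factors = tmm_factors(table)
    lib = table.counts.sum(axis=0)
    offset = np.log(lib.to_numpy(dtype=float)
                    * factors.reindex(table.counts.columns).to_numpy())
    x = (meta[group_column] == g2).to_numpy(dtype=float)
    eff_lib = lib.to_numpy(dtype=float) * factors.reindex(
        table.counts.columns).to_numpy()
    norm = table.counts.to_numpy(dtype=float) / eff_lib * eff_lib.mean()

    rows = {}
    excluded = []
    for i, taxon in enumerate(table.counts.index):
        y = table.counts.iloc[i].to_numpy(dtype=np.int64)
        if y.sum() == 0:
            excluded.append(str(taxon))
            continue
        beta, p = _nb_wald_one(y.astype(float), x, offset)
        log2fc = beta / math.log(2.0)
        m1 = norm[i, x == 0].mean()
        m2 = norm[i, x == 1].mean()
        rows[taxon] = {
            "max_group_mean": max(m1, m2),
            "log2_fold_change": log2fc,
            "fold_change": fold_change(log2fc) if np.isfinite(log2fc)
            else np.nan,
            "wald_p": p,
        }
    if excluded:
        log.info("daa_wald: excluded %d all-zero taxa", len(excluded))
    out = pd.DataFrame(rows).T
    if len(out):
        p_arr = out["wald_p"].to_numpy(dtype=float)
        fdr = np.full_like(p_arr, np.nan)
        ok = np.isfinite(p_arr)
        if ok.any():
            fdr[ok] = multipletests(p_arr[ok], method="fdr_bh")[1]
        out["fdr_p"] = fdr
    return DAAResult(table=out, group_pair=(g1, g2), excluded=excluded)


# ------------------------------------------------------------- comparisons

#: the six study contrasts; per-site ones run once per microbiome site
CONTRASTS = (
    ("control_vs_treated_3h", True, {"time": "t3h"}, "group",
     ("control", "treated")),
    ("control_vs_treated_24h", True, {"time": "t24h"}, "group",
     ("control", "treated")),
    ("control_3h_vs_24h", True, {"group": "control"}, "time",
     ("t3h", "t24h")),
    ("treated_3h_vs_24h", True, {"group": "treated"}, "time",
     ("t3h", "t24h")),
    ("all_sites_control_vs_treated_3h", False, {"time": "t3h"}, "group",
     ("control", "treated")),
    ("all_sites_control_vs_treated_24h", False, {"time": "t24h"}, "group",
     ("control", "treated")),
)


def run_comparisons(table: OTUTable, design: pd.DataFrame,
                    sites: tuple[str, ...] | None = None,
                    ) -> dict[tuple[str, str | None], DAAResult]:
    """Run the standard differential-abundance contrasts.

    Six contrast families: control vs treated at each time and 3 h vs
    24 h within each condition (per site), plus pooled all-sites control
    vs treated at each time. Each contrast gets its own TMM factors and
    its own FDR family. Contrasts with fewer than two samples per group
    are skipped with a warning. Keys are ``(contrast name, site)`` with
    ``site=None`` for the pooled contrasts.
    """
    meta = design[design["sample_id"].isin(table.counts.columns)]
    if sites is None:
        sites = tuple(sorted(meta["site"].unique()))
    out: dict[tuple[str, str | None], DAAResult] = {}
    for name, per_site, filt, column, pair in CONTRASTS:
        site_list = sites if per_site else (None,)
        for site in site_list:
            sub = meta
            if site is not None:
                sub = sub[sub["site"] == site]
            for key, val in filt.items():
                sub = sub[sub[key] == val]
            cols = [s for s in table.counts.columns
                    if s in set(sub["sample_id"])]
            sub_table = OTUTable(counts=table.counts[cols],
                                 taxonomy=table.taxonomy)
            try:
                out[(name, site)] = daa_wald(sub_table, sub, pair,
                                             group_column=column)
            except MicrobiomeError as err:
                log.warning("contrast %s (site=%s) skipped: %s", name, site,
                            err)
    return out


def diversity_report(table: OTUTable, design: pd.DataFrame,
                     depth: int = RAREFACTION_DEPTH,
                     n_perm: int = 999, seed: int = 0,
                     rarefy_first: bool = True) -> dict:
    """Alpha/beta diversity summary for one sample set.

    Rarefies to ``depth`` (seeded, optional), computes per-sample alpha
    indices with Kruskal-Wallis tests across groups, and Bray-Curtis
    PCoA coordinates with a PERMANOVA test.
    """
    work = rarefy(table, depth, seed) if rarefy_first else table
    alpha = alpha_diversity_table(work)
    meta = design.set_index("sample_id").reindex(alpha.index)
    groups = (meta["group"] + "_" + meta["time"]).to_numpy()
    kw = {col: kruskal_wallis(alpha[col].to_numpy(), groups)
          for col in alpha.columns}
    dm = bray_curtis(work)
    coords, eig = pcoa(dm)
    stat, p = permanova(dm, groups, n_perm=n_perm, seed=seed)
    return {
        "alpha": alpha,
        "kruskal_wallis": pd.DataFrame(kw, index=["H", "p"]).T,
        "pcoa_coordinates": coords,
        "pcoa_eigenvalues": eig,
        "permanova": {"pseudo_F": stat, "p": p},
    }


def relative_abundance(table: OTUTable, decimals: int = 2) -> pd.DataFrame:
    """Mean percent relative abundance per taxon, sorted descending."""
    rel = table.counts / table.counts.sum(axis=0)
    out = (100.0 * rel.mean(axis=1)).round(decimals).sort_values(
        ascending=False)
    return out.to_frame("abundance_pct")
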