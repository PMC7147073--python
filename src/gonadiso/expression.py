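"""FPKM normalisation, sex-biased expression classification, differential
expression and pathway enrichment.

Expression is summarised as FPKM (fragments per kilobase of transcript per
million mapped fragments); a transcript counts as expressed in a tissue
group when its mean FPKM across that group's replicates exceeds 0.1.
Group-specific transcripts are binned by abundance (0.1-2 / 2-10 / >10).

Differential expression uses an exact conditional test on per-group count
sums after median-of-ratios library-size normalisation: Poisson when the
dispersion is zero, negative binomial with a moderated tagwise dispersion
otherwise.  Calls require |log2FC| > 1 (strict) and Benjamini-Hochberg
FDR < 0.05; transcripts expressed in exactly one group carry an infinite
fold-change sentinel ("inf") instead of a finite log2FC.

Pathway enrichment is the one-sided hypergeometric upper tail with BH
correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from gonadiso.core_io import CountMatrix, PathwayMap, SampleDesign

FPKM_THRESHOLD = 0.1
FC_THRESHOLD = 1.0
FDR_THRESHOLD = 0.05
PSEUDOCOUNT_FPKM = 0.1

NOT_EXPRESSED = "not_expressed"
SHARED = "shared"

BIN_LOW = "low"    # 0.1 < FPKM < 2
BIN_MID = "mid"    # 2 < FPKM < 10
BIN_HIGH = "high"  # FPKM > 10


# ---------------------------------------------------------------------------
# FPKM
# ---------------------------------------------------------------------------

def compute_fpkm(counts: CountMatrix, lengths: pd.Series) -> pd.DataFrame:
    """FPKM[i, s] = count[i, s] * 1e9 / (length_i * librarySize_s)."""
    lengths = lengths.reindex(counts.transcript_ids)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()][0]
        raise ValueError(f"no length for transcript {missing!r}")
    if (lengths <= 0).any():
        raise ValueError("transcript lengths must be positive")
    lib = counts.library_sizes()
    zero = lib.index[lib == 0]
    if len(zero):
        raise ValueError(f"zero library size for sample {zero[0]!r}")
    return counts.df.mul(1e9).div(lib, axis=1).div(lengths, axis=0)


# ---------------------------------------------------------------------------
# Specificity classification
# ---------------------------------------------------------------------------

@dataclass
class ExpressionCategory:
    """Per-transcript category and abundance bin plus bookkeeping summaries."""

    category: pd.Series     # not_expressed | <groupA>_specific | <groupB>_specific | shared
    abundance_bin: pd.Series  # low/mid/high for specific transcripts, else NA
    group_means: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        counts = self.category.value_counts()
        rows = []
        for cat in counts.index:
            row = {"category": cat, "n": int(counts[cat])}
            if cat.endswith("_specific"):
                bins = self.abundance_bin[self.category == cat].value_counts()
                for b in (BIN_LOW, BIN_MID, BIN_HIGH):
                    row[b] = int(bins.get(b, 0))
            rows.append(row)
        return pd.DataFrame(rows)


def abundance_bin(fpkm: float, threshold: float = FPKM_THRESHOLD) -> str | None:
    """Bin a group-mean FPKM.  Boundary values (exactly 2 or 10) fall into
    the lower bin; the printed intervals are open so a convention is needed."""
    if fpkm <= threshold:
        return None
    if fpkm <= 2:
        return BIN_LOW
    if fpkm <= 10:
        return BIN_MID
    return BIN_HIGH


def classify_expression(fpkm: pd.DataFrame, design: SampleDesign,
                        threshold: float = FPKM_THRESHOLD) -> ExpressionCategory:
    """Classify each transcript from group-mean FPKM.

    A transcript is expressed in a group iff mean FPKM > threshold;
    categories are not-expressed / A-specific / B-specific / shared, and
    group-specific transcripts are binned by their on-group mean.
    """
    ga, gb = design.group_labels
    mean_a = fpkm[design.samples_of(ga)].mean(axis=1)
    mean_b = fpkm[design.samples_of(gb)].mean(axis=1)
    means = pd.DataFrame({ga: mean_a, gb: mean_b})
    cats = pd.Series(index=fpkm.index, dtype=object)
    bins = pd.Series(index=fpkm.index, dtype=object)
    on_a = mean_a > threshold
    on_b = mean_b > threshold
    cats[~on_a & ~on_b] = NOT_EXPRESSED
    cats[on_a & on_b] = SHARED
    cats[on_a & ~on_b] = f"{ga}_specific"
    cats[~on_a & on_b] = f"{gb}_specific"
    on_mean = mean_a.where(on_a & ~on_b, mean_b)
    specific = (on_a ^ on_b)
    bins[specific & (on_mean <= 2)] = BIN_LOW
    bins[specific & (on_mean > 2) & (on_mean <= 10)] = BIN_MID
    bins[specific & (on_mean > 10)] = BIN_HIGH
    return ExpressionCategory(cats, bins, means)


# ---------------------------------------------------------------------------
# Library-size normalisation
# ---------------------------------------------------------------------------

def size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors; falls back to total-count scaling when
    fewer than 50 transcripts have all-positive counts."""
    df = counts.df
    positive = df[(df > 0).all(axis=1)]
    if len(positive) >= 50:
        log_geo = np.log(positive).mean(axis=1)
        ratios = np.log(positive).sub(log_geo, axis=0)
        sf = np.exp(ratios.median(axis=0))
    else:
        lib = counts.library_sizes().astype(float)
        sf = lib / np.exp(np.log(lib).mean())
    return sf / np.exp(np.log(sf).mean())


# ---------------------------------------------------------------------------
# Exact conditional NB / Poisson test
# ---------------------------------------------------------------------------

def _moment_dispersions(norm: pd.DataFrame, design: SampleDesign) -> pd.Series:
    """Method-of-moments tagwise dispersions moderated toward the common one.

    For NB, var = mu + phi mu^2, so phi-hat = (s^2 - mu) / mu^2 pooled over
    the two groups.  Tagwise estimates from 3-4 replicates are noisy; they
    are shrunk toward the common (median) dispersion with weight ~20 prior
    degrees of freedom, in the spirit of moderated-dispersion DE testing.
    """
    ga, gb = design.group_labels
    phis = []
    weights = []
    for g in (ga, gb):
        sub = norm[design.samples_of(g)]
        n = sub.shape[1]
        if n < 2:
            continue
        mu = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi = (s2 - mu) / mu**2
        phis.append(phi.replace([np.inf, -np.inf], np.nan))
        weights.append(n - 1)
    if not phis:
        raise ValueError("dispersion estimation needs >= 2 replicates in a group; "
                         "use dispersion_mode='poisson' or a fixed value")
    tag_raw = sum(p.fillna(0) * w for p, w in zip(phis, weights)) / sum(weights)
    # common dispersion: mean of the raw (unclipped) tagwise estimates —
    # the raw moment estimator is ~unbiased while median/clipping skew low
    common = max(float(np.nanmean(tag_raw)), 0.0)
    tag = tag_raw.clip(lower=0)
    prior_df = 20.0
    resid_df = float(sum(weights))
    moderated = (resid_df * tag + prior_df * common) / (resid_df + prior_df)
    return moderated.clip(lower=0)


def _exact_conditional_p(ya: int, yb: int, na: float, nb: float,
                         phi: float) -> float:
    """Two-sided exact conditional test of equal group means.

    Conditions on the total t = ya + yb.  Group sums are modelled as
    NB(mean n_g * mu, dispersion phi / n_g) (the sum of n_g i.i.d. NB
    replicates); with phi = 0 this reduces to the binomial split
    Binomial(t, na / (na + nb)).  The two-sided p sums the probabilities of
    all splits no more probable than the observed one.
    """
    t = ya + yb
    if t == 0:
        return 1.0
    k = np.arange(t + 1)
    if phi <= 0:
        logp = stats.binom.logpmf(k, t, na / (na + nb))
    else:
        mu = t / (na + nb)
        ra, rb = na / phi, nb / phi
        pa = ra / (ra + na * mu)
        pb = rb / (rb + nb * mu)
        logp = (stats.nbinom.logpmf(k, ra, pa)
                + stats.nbinom.logpmf(t - k, rb, pb))
        logp -= logsumexp_stable(logp)
    obs = logp[ya]
    keep = logp <= obs + 1e-10  # tolerate fp ties
    p = float(np.exp(logsumexp_stable(logp[keep])))
    return min(p, 1.0)


def logsumexp_stable(x: np.ndarray) -> float:
    m = np.max(x)
    return float(m + np.log(np.sum(np.exp(x - m))))


def nb_de_test(counts: CountMatrix, design: SampleDesign,
               dispersion_mode: str | float = "auto") -> pd.DataFrame:
    """Per-transcript exact conditional test of group mean equality.

    ``dispersion_mode``: "auto" (moderated tagwise moment estimates),
    "poisson" (phi = 0), or a fixed float.  Counts are library-size
    normalised (median-of-ratios), scaled to the mean library, and rounded
    before the conditional test.  Returns log2FC (B over A, with a
    pseudocount), raw p, and the group mean normalised counts.
    """
    sf = size_factors(counts)
    norm = counts.df.div(sf, axis=1)
    ga, gb = design.group_labels
    sa, sb = design.samples_of(ga), design.samples_of(gb)
    na, nb = len(sa), len(sb)
    if dispersion_mode == "poisson":
        phis = pd.Series(0.0, index=counts.transcript_ids)
    elif dispersion_mode == "auto":
        phis = _moment_dispersions(norm, design)
    else:
        phis = pd.Series(float(dispersion_mode), index=counts.transcript_ids)
    ya = norm[sa].sum(axis=1).round().astype(int)
    yb = norm[sb].sum(axis=1).round().astype(int)
    mean_a = norm[sa].mean(axis=1)
    mean_b = norm[sb].mean(axis=1)
    pseudo = 0.5
    log2fc = np.log2((mean_b + pseudo) / (mean_a + pseudo))
    pvals = pd.Series(index=counts.transcript_ids, dtype=float)
    for tid in counts.transcript_ids:
        a, b = int(ya[tid]), int(yb[tid])
        if a + b == 0:
            pvals[tid] = 1.0
            continue
        pvals[tid] = _exact_conditional_p(a, b, na, nb, float(phis[tid]))
    out = pd.DataFrame({
        "mean_a": mean_a, "mean_b": mean_b,
        "log2fc": log2fc, "p": pvals, "dispersion": phis,
    })
    out.loc[(ya == 0) & (yb == 0), "log2fc"] = 0.0
    return out


# ---------------------------------------------------------------------------
# Multiple testing + DE classification
# ---------------------------------------------------------------------------

def bh_adjust(p: pd.Series | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, idempotent)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


@dataclass
class DEResult:
    table: pd.DataFrame   # log2fc, p, fdr, call, tissue_specific
    group_labels: tuple[str, str]

    @property
    def de_ids(self) -> list[str]:
        return list(self.table.index[self.table["call"] != "not_DE"])


def de_classify(stats_table: pd.DataFrame, categories: ExpressionCategory,
                design: SampleDesign, fc_threshold: float = FC_THRESHOLD,
                fdr_threshold: float = FDR_THRESHOLD) -> DEResult:
    """Call DE transcripts at |log2FC| > fc_threshold (strict) and
    FDR < fdr_threshold; flag group-specific expression as "inf".

    A transcript whose mean FPKM exceeds the expression threshold in exactly
    one group keeps its direction but reports an infinite-ratio sentinel
    instead of the finite pseudocounted log2FC.
    """
    ga, gb = design.group_labels
    fdr = bh_adjust(stats_table["p"])
    table = stats_table.copy()
    table["fdr"] = fdr
    # fold change from FPKM group means with a 0.1 pseudocount on both sides
    means = categories.group_means.reindex(table.index)
    table["log2fc"] = np.log2((means[gb] + PSEUDOCOUNT_FPKM)
                              / (means[ga] + PSEUDOCOUNT_FPKM))
    specific = categories.category.reindex(table.index)
    tissue_specific = specific.isin([f"{ga}_specific", f"{gb}_specific"])
    call = pd.Series("not_DE", index=table.index)
    sig = (table["log2fc"].abs() > fc_threshold) & (table["fdr"] < fdr_threshold)
    call[sig & (table["log2fc"] > 0)] = f"up_{gb}"
    call[sig & (table["log2fc"] < 0)] = f"up_{ga}"
    table["call"] = call
    table["tissue_specific"] = tissue_specific & (call != "not_DE")
    table["log2fc_display"] = [
        ("inf" if spec else f"{fc:.3f}")
        for fc, spec in zip(table["log2fc"], table["tissue_specific"])
    ]
    return DEResult(table, (ga, gb))


# ---------------------------------------------------------------------------
# Enrichment + panel cross-tabulation
# ---------------------------------------------------------------------------

def pathway_enrichment(de_ids, universe_ids, pathways: PathwayMap,
                       alpha: float = 0.05) -> pd.DataFrame:
    """One-sided hypergeometric upper-tail enrichment with BH correction.

    p = P[X >= overlap] for X ~ Hypergeom(universe, pathway-in-universe,
    DE-set size); a pathway is enriched iff corrected p < alpha.
    """
    de = set(de_ids)
    universe = set(universe_ids)
    if not de <= universe:
        raise ValueError("DE set must be a subset of the universe")
    n_u = len(universe)
    n_de = len(de)
    rows = []
    for pid, members in sorted(pathways.pathways.items()):
        in_universe = members & universe
        k = len(in_universe & de)
        m = len(in_universe)
        if n_de == 0:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(k - 1, n_u, m, n_de))
        rows.append({"pathway": pid, "overlap": k, "pathway_size": m,
                     "de_size": n_de, "universe_size": n_u, "p": p})
    df = pd.DataFrame(rows).set_index("pathway")
    df["p_adj"] = bh_adjust(df["p"]) if len(df) else []
    df["enriched"] = df["p_adj"] < alpha
    return df


def crosstab_panel(de: DEResult, terms: PathwayMap,
                   universe_ids=None) -> pd.DataFrame:
    """Per term: total member transcripts and members called DE."""
    de_set = set(de.de_ids)
    if universe_ids is not None:
        universe = set(universe_ids)
        for pid, members in terms.pathways.items():
            if not set(members) <= universe:
                raise ValueError(f"term {pid!r} has members outside the universe")
    rows = []
    for pid, members in sorted(terms.pathways.items()):
        rows.append({"term": pid, "n_unigenes": len(members),
                     "n_DEUs": len(set(members) & de_set)})
    return pd.DataFrame(rows).set_index("term")
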