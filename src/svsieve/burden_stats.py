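"""Per-sample burden matrices and proband-versus-sibling comparisons.

Two complementary tests are provided. The chi-square burden test compares
total event counts between groups on a 2x2 table of (events, sample slots)
per group — the construction that reproduces the direction and magnitude of
published SV-burden odds ratios — with optional Yates continuity correction
and a Haldane–Anscombe 0.5 correction for zero cells in the odds ratio. The
Mann–Whitney U test compares per-sample count distributions with a
tie-corrected normal approximation (Z > 0 means probands higher) and an
exact enumeration p-value when the smaller group has at most 8 samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import ABSENT, CARRIER_CODES
from .rare_filter import RareSVTable

BASE_CATEGORIES = ("ALL", "DEL", "INS", "EXON", "INTRON", "INTER", "REG", "brainREG", "NDD", "PAT", "MAT")


def infer_transmission(rare: RareSVTable, ped) -> dict:
    """(child, sv_id) -> 'father'/'mother' when unambiguous from parental
    genotypes (exactly one parent carries), else absent."""
    table = rare.table
    si = {s: i for i, s in enumerate(table.samples)}
    out = {}
    for e in rare.entries.itertuples():
        fa, mo = ped.parents_of(e.child)
        fgt = int(table.genotypes[e.row, si[fa]])
        mgt = int(table.genotypes[e.row, si[mo]])
        f_car, m_car = fgt in CARRIER_CODES, mgt in CARRIER_CODES
        if f_car and not m_car:
            out[(e.child, e.sv_id)] = "father"
        elif m_car and not f_car:
            out[(e.child, e.sv_id)] = "mother"
    return out


def per_sample_counts(
    rare: RareSVTable,
    annotations: pd.DataFrame,
    ped,
    categories: Sequence[str] = BASE_CATEGORIES,
    transmission: Optional[Mapping[tuple, str]] = None,
    x_variants: bool = True,
) -> pd.DataFrame:
    """Integer count per child per burden category (plus X-restricted columns).

    ``annotations`` is the annotate_svs output keyed by sv_id; PAT/MAT
    columns need a transmission map (inferred from parental genotypes when
    not given).
    """
    ann = annotations.set_index("sv_id")
    if transmission is None:
        transmission = infer_transmission(rare, ped)
    children = ped.children
    cols = list(categories) + ([f"X_{c}" for c in categories] if x_variants else [])
    counts = pd.DataFrame(0, index=pd.Index(children, name="sample"), columns=cols, dtype=int)

    for e in rare.entries.itertuples():
        rec = rare.table.rows[e.row]
        a = ann.loc[e.sv_id] if e.sv_id in ann.index else None
        hits = {"ALL"}
        if rec.svtype in ("DEL", "INS"):
            hits.add(rec.svtype)
        if a is not None:
            hits.add(a["functional_class"])  # EXON/INTRON/INTER
            for flag, col in (("REG", "REG"), ("brainREG", "brainREG"), ("NDD_gene", "NDD")):
                if a.get(flag, False):
                    hits.add(col)
        t = transmission.get((e.child, e.sv_id))
        if t == "father":
            hits.add("PAT")
        elif t == "mother":
            hits.add("MAT")
        for h in hits & set(categories):
            counts.loc[e.child, h] += 1
            if x_variants and e.chrom_class == "X":
                counts.loc[e.child, f"X_{h}"] += 1

    counts["group"] = [ped.role_of(c) for c in children]
    counts["sex"] = [ped.sexes[c] for c in children]
    return counts


@dataclass(frozen=True)
class Chi2Result:
    chi2: float
    odds_ratio: float
    p: float
    defined: bool = True


def chi2_burden(
    events_proband: int,
    n_proband_samples: int,
    events_sibling: int,
    n_sibling_samples: int,
    yates: bool = True,
) -> Chi2Result:
    """Chi-square comparison of event totals on the 2x2 table
    [[events_p, N_p], [events_s, N_s]]."""
    a, b = float(events_proband), float(n_proband_samples)
    c, d = float(events_sibling), float(n_sibling_samples)
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be nonnegative")
    if (a + b) == 0 and (c + d) == 0:
        return Chi2Result(float("nan"), float("nan"), float("nan"), defined=False)
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        chi2 = 0.0
    else:
        dev = abs(a * d - b * c)
        if yates:
            dev = max(dev - n / 2.0, 0.0)
        chi2 = n * dev * dev / denom
    if 0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5  # Haldane–Anscombe
    orr = (a * d) / (b * c)
    p = float(stats.chi2.sf(chi2, df=1)) if denom else float("nan")
    return Chi2Result(chi2, orr, p, defined=bool(denom))


@dataclass(frozen=True)
class MWUResult:
    z: float
    p: float  # exact when available, else normal approximation
    p_normal: float
    p_exact: Optional[float] = None
    u: float = float("nan")


def _u_statistic(ranks: np.ndarray, idx: Sequence[int], n_x: int) -> float:
    return float(ranks[list(idx)].sum() - n_x * (n_x + 1) / 2.0)


def mwu_burden(counts_proband: Sequence[float], counts_sibling: Sequence[float]) -> MWUResult:
    """Two-sided Mann–Whitney U comparison of per-sample counts."""
    x = np.asarray(counts_proband, float)
    y = np.asarray(counts_sibling, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups need at least one value")
    n_x, n_y = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u = _u_statistic(ranks, range(n_x), n_x)
    mean_u = n_x * n_y / 2.0
    n = n_x + n_y
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))) if n > 1 else 0.0
    var_u = n_x * n_y / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:
        z = 0.0
        p_norm = 1.0
    else:
        z = (u - mean_u) / np.sqrt(var_u)
        p_norm = float(2.0 * stats.norm.sf(abs(z)))
    p_exact = None
    if min(n_x, n_y) <= 8:
        obs = abs(u - mean_u)
        extreme = 0
        total = comb(n, n_x)
        for idx in combinations(range(n), n_x):
            if abs(_u_statistic(ranks, idx, n_x) - mean_u) >= obs - 1e-12:
                extreme += 1
        p_exact = extreme / total
    return MWUResult(z=float(z), p=p_exact if p_exact is not None else p_norm,
                     p_normal=p_norm, p_exact=p_exact, u=u)


def adjust_pvalues(p_values: Sequence[float], method: str = "bonferroni",
                   m: Optional[int] = None) -> list:
    """Bonferroni family correction: min(1, m * p); order-preserving."""
    if method != "bonferroni":
        raise ValueError(f"unsupported method {method!r}")
    ps = list(p_values)
    for p in ps:
        if not (np.isnan(p) or 0.0 <= p <= 1.0):
            raise ValueError("p-values must be in [0,1]")
    m = m if m is not None else len(ps)
    return [min(1.0, m * p) if not np.isnan(p) else p for p in ps]


def burden_tests(
    counts: pd.DataFrame,
    categories: Optional[Sequence[str]] = None,
    yates: bool = True,
) -> pd.DataFrame:
    """One row per category: totals, chi-square/OR, MWU Z, nominal and
    Bonferroni-adjusted p. ``counts`` is the per_sample_counts output."""
    pro = counts[counts["group"] == "proband"]
    sib = counts[counts["group"] == "sibling"]
    cats = list(categories) if categories is not None else [
        c for c in counts.columns if c not in ("group", "sex")
    ]
    rows = []
    for cat in cats:
        ep, es = int(pro[cat].sum()), int(sib[cat].sum())
        chi = chi2_burden(ep, len(pro), es, len(sib), yates=yates)
        mwu = mwu_burden(pro[cat].to_numpy(), sib[cat].to_numpy()) if len(pro) and len(sib) else None
        rows.append(
            {
                "category": cat,
                "n_proband": len(pro),
                "n_sibling": len(sib),
                "total_proband_SVs": ep,
                "total_sibling_SVs": es,
                "chi2": chi.chi2,
                "odds_ratio": chi.odds_ratio,
                "p_nominal": chi.p,
                "z_mwu": mwu.z if mwu else float("nan"),
                "p_mwu": mwu.p if mwu else float("nan"),
            }
        )
    df = pd.DataFrame(rows)
    df["p_adjusted"] = adjust_pvalues(df["p_nominal"].tolist())
    return df


def filtering_efficiency_report(
    per_child_validated_mean: float,
    per_child_rare_mean: float,
) -> dict:
    """Percent of validated SVs per child excluded by control filtering."""
    if per_child_validated_mean <= 0:
        raise ValueError("validated mean must be positive")
    frac = 1.0 - per_child_rare_mean / per_child_validated_mean
    return {
        "validated_per_child": per_child_validated_mean,
        "rare_per_child": per_child_rare_mean,
        "percent_excluded": int(np.floor(100.0 * frac + 0.5)),  # round half-up
        "fraction_excluded": frac,
    }


def ratio_percent(k: float, n: float, decimals: int = 1) -> float:
    """Generic k/n percentage, rounded half-up at the given precision."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    scale = 10**decimals
    return float(np.floor(100.0 * k / n * scale + 0.5) / scale)
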