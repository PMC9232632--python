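"""Decision statistics for the screen.

Covers the translational layer: lymphocyte-referenced chemosensitivity
calls, population-level triplet-minus-backbone benefit testing with FDR
control, per-patient optimal-combination nomination, the exact 2x2 test
used for remission association, and a chemogenomic Mann-Whitney scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class TestSummary:
    test: str
    statistic: float
    p_value: float
    q_value: float | None = None
    group_sizes: tuple = ()
    method: str = ""

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of range: {self.p_value}")
        if self.q_value is not None and self.q_value < self.p_value - 1e-12:
            raise ValueError("q-value below p-value")


@dataclass
class SensitivityCall:
    """Chemosensitivity of one patient's population vs their lymphocytes."""

    patient: str
    population: str
    aoc_population: float
    aoc_lymphocytes: float
    call: str = field(init=False)

    def __post_init__(self) -> None:
        if self.population not in ("bulk", "lsc"):
            raise ValueError("population must be 'bulk' or 'lsc'")
        # strictly greater activity than the internal lymphocyte reference
        # is sensitive; equality counts as resistant
        self.call = ("sensitive"
                     if self.aoc_population > self.aoc_lymphocytes
                     else "resistant")


def sensitivity_call(aoc_pop: float, aoc_lymph: float, patient: str = "",
                     population: str = "bulk") -> SensitivityCall:
    """Lymphocyte-referenced chemosensitivity call (ties -> resistant)."""
    return SensitivityCall(patient=patient, population=population,
                           aoc_population=float(aoc_pop),
                           aoc_lymphocytes=float(aoc_lymph))


# ---------------------------------------------------------------------------
# statistical kernels


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    Elementwise q >= p, monotone under the step-up reconstruction, and
    invariant (per element) to input permutation.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def mann_whitney(group_a, group_b) -> TestSummary:
    """Two-sided Mann-Whitney U test.

    Uses the exact null distribution when min(n) <= 8 and the pooled data
    are tie-free, and the tie-corrected normal approximation (with
    continuity correction) otherwise; the method used is recorded.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(a.size, b.size) <= 8 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestSummary(test="mann_whitney", statistic=float(res.statistic),
                       p_value=float(res.pvalue),
                       group_sizes=(a.size, b.size), method=method)


def fisher_exact_2x2(table) -> TestSummary:
    """Two-sided Fisher exact test on a 2x2 contingency table.

    With margins fixed, the two-sided p-value is the total hypergeometric
    probability of every table whose probability does not exceed that of the
    observed table.  The enumeration runs in exact integer arithmetic
    (probabilities compared through their integer numerators at the common
    denominator C(n, c1)), so equally probable tables on the opposite tail
    are included without any floating-point tie tolerance.
    """
    import math

    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(t < 0) or np.any(t != np.floor(t)):
        raise ValueError("cells must be non-negative integers")
    t = t.astype(int)
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if n == 0:
        raise ValueError("table margins must be positive")
    num_obs = math.comb(r1, a) * math.comb(n - r1, c1 - a)
    total = 0
    for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        num = math.comb(r1, k) * math.comb(n - r1, c1 - k)
        if num <= num_obs:
            total += num
    p = total / math.comb(n, c1)
    odds = np.inf if b * c == 0 else (a * d) / (b * c)
    return TestSummary(test="fisher_exact", statistic=float(odds),
                       p_value=min(p, 1.0), group_sizes=(r1, c + d),
                       method="exact-integer-enumeration")


# ---------------------------------------------------------------------------
# combination benefit


@dataclass
class CombinationBenefit:
    """Population-level benefit of one third agent over the backbone."""

    agent: str
    n: int
    mean_delta: float
    t_statistic: float
    p_value: float
    q_value: float
    degenerate: bool = False
    deltas: dict = field(default_factory=dict)  # patient -> delta


def combination_benefit(aoc_table: pd.DataFrame,
                        backbone: str = "backbone") -> list:
    """Test each third agent's LSC-activity benefit over the backbone.

    ``aoc_table`` is long-form with columns (patient, arm, aoc) where arm is
    ``backbone`` or an agent id.  Per agent, deltas = AOC(triplet) -
    AOC(backbone) over patients with both values; a one-sample two-sided t
    test of the deltas against 0 is BH-corrected across agents.  Agents with
    n < 3 are reported without p/q; zero-variance deltas are flagged
    degenerate with p/q = NaN.
    """
    required = {"patient", "arm", "aoc"}
    if not required.issubset(aoc_table.columns):
        raise ValueError(f"aoc_table needs columns {sorted(required)}")
    wide = aoc_table.pivot_table(index="patient", columns="arm", values="aoc")
    if backbone not in wide.columns:
        raise ValueError(f"no backbone arm {backbone!r} in the table")
    agents = sorted(c for c in wide.columns if c != backbone)
    results = []
    for agent in agents:
        deltas = (wide[agent] - wide[backbone]).dropna()
        n = int(deltas.size)
        mean = float(deltas.mean()) if n else np.nan
        tstat = pval = np.nan
        degenerate = False
        if n >= 3:
            if float(deltas.std(ddof=1)) == 0.0:
                degenerate = True
            else:
                res = sps.ttest_1samp(deltas.to_numpy(), popmean=0.0)
                tstat, pval = float(res.statistic), float(res.pvalue)
        results.append(CombinationBenefit(
            agent=agent, n=n, mean_delta=mean, t_statistic=tstat,
            p_value=pval, q_value=np.nan, degenerate=degenerate,
            deltas=deltas.to_dict()))
    tested = [r for r in results if np.isfinite(r.p_value)]
    if tested:
        qs = bh_fdr([r.p_value for r in tested])
        for r, q in zip(tested, qs):
            r.q_value = float(q)
    return results


def benefit_frame(results: list) -> pd.DataFrame:
    return pd.DataFrame([{
        "agent": r.agent, "n": r.n, "mean_delta": r.mean_delta,
        "t": r.t_statistic, "p": r.p_value, "q": r.q_value,
        "degenerate": r.degenerate} for r in results])


def nominate_optimal(results: list) -> pd.DataFrame:
    """Per-patient optimal third agent by argmax LSC-activity delta.

    A patient whose deltas are all <= 0 is nominated "no benefit"; exact
    ties go to the lexicographically smallest agent id and are flagged.
    """
    per_patient = {}
    for r in results:
        for patient, delta in r.deltas.items():
            per_patient.setdefault(patient, {})[r.agent] = delta
    if not per_patient:
        raise ValueError("no per-patient deltas available")
    rows = []
    for patient in sorted(per_patient):
        deltas = per_patient[patient]
        best = max(deltas.values())
        if best <= 0:
            rows.append({"patient": patient, "nomination": "no benefit",
                         "delta": best, "tie": False})
            continue
        winners = sorted(a for a, d in deltas.items() if d == best)
        rows.append({"patient": patient, "nomination": winners[0],
                     "delta": best, "tie": len(winners) > 1})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# chemogenomics


def chemogenomic_scan(activity: pd.DataFrame, mutations: pd.DataFrame,
                      min_group: int = 3):
    """Mann-Whitney scan of drug activity against mutation status.

    ``activity`` is long-form (patient, treatment, readout, aoc);
    ``mutations`` is patients x genes with 0/1 entries.  Each
    (treatment, gene, readout) pair with at least ``min_group`` patients per
    genotype is tested (mutant vs wild-type AOC) and BH-corrected across the
    whole scan; under-powered or constant-genotype pairs are skipped and
    listed.  Returns (results frame, skipped list).
    """
    required = {"patient", "treatment", "readout", "aoc"}
    if not required.issubset(activity.columns):
        raise ValueError(f"activity needs columns {sorted(required)}")
    rows, skipped = [], []
    for (treatment, readout), grp in activity.groupby(["treatment", "readout"],
                                                      sort=True):
        vals = grp.set_index("patient")["aoc"]
        for gene in sorted(mutations.columns):
            status = mutations[gene].reindex(vals.index).dropna()
            common = vals.loc[status.index]
            mut = common[status == 1]
            wt = common[status == 0]
            if min(mut.size, wt.size) < min_group:
                skipped.append((treatment, gene, readout, "under-powered"))
                continue
            res = mann_whitney(mut.to_numpy(), wt.to_numpy())
            rows.append({
                "treatment": treatment, "gene": gene, "readout": readout,
                "n_mut": mut.size, "n_wt": wt.size,
                "mean_mut": float(mut.mean()), "mean_wt": float(wt.mean()),
                "U": res.statistic, "p": res.p_value, "method": res.method})
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_fdr(out["p"].to_numpy())
    return out, skipped
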