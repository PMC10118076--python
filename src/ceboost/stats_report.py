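"""Statistical layer: normality checks, paired comparisons, agreement, reports.

Routing rule for the paired conventional-vs-boosted comparisons: continuous
metrics use the paired-samples t-test when Shapiro–Wilk does not reject
normality of the differences (p >= 0.05), otherwise the Wilcoxon signed-rank
test; FWHM and ordinal (Likert) scores always use Wilcoxon.  All p-values
are two-sided and significance is 0.05.

The Wilcoxon implementation follows the classical recipe — zero differences
dropped, ties mid-ranked — with an exact null distribution (dynamic program
over doubled ranks, equivalent to enumerating all 2^n sign assignments) for
n <= 15 and a tie-corrected normal approximation with continuity correction
beyond that.  scipy's exact method declines ties and zeros, hence the
in-house tail computation.

Inter-observer agreement uses unweighted Cohen's kappa on the pooled 5-level
scale (weighted kappa available via ``weights``), binned as: >= 0.81
excellent, 0.61–0.80 substantial, 0.41–0.60 moderate, 0.21–0.40 fair,
< 0.21 poor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateInputError

__all__ = [
    "PairedSample",
    "RatingTable",
    "KappaResult",
    "normality_check",
    "paired_t",
    "wilcoxon_signed_rank",
    "cohen_kappa",
    "interpret_kappa",
    "compare_report",
]

LIKERT_LEVELS = (1, 2, 3, 4, 5)

#: metrics compared with Wilcoxon regardless of normality (ordinal or
#: conventionally non-parametric)
ALWAYS_WILCOXON = ("fwhm_mm", "likert")


@dataclass(frozen=True)
class PairedSample:
    """Per-case paired measurements (e.g. conventional vs boosted)."""

    values_a: np.ndarray
    values_b: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        a = np.asarray(self.values_a, dtype=float)
        b = np.asarray(self.values_b, dtype=float)
        object.__setattr__(self, "values_a", a)
        object.__setattr__(self, "values_b", b)
        if a.shape != b.shape or a.ndim != 1 or a.size < 3:
            raise DegenerateInputError(
                f"paired sample {self.label!r}: need two aligned vectors of length >= 3"
            )

    @property
    def differences(self) -> np.ndarray:
        return self.values_a - self.values_b


@dataclass
class RatingTable:
    """Two readers' ordinal 1–5 scores per case and criterion.

    ``scores`` is a long-format frame with columns case_id, reader,
    criterion, score (and optionally variant).
    """

    scores: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"case_id", "reader", "criterion", "score"}
        missing = required - set(self.scores.columns)
        if missing:
            raise DegenerateInputError(f"rating table missing columns {sorted(missing)}")
        if not self.scores["score"].isin(LIKERT_LEVELS).all():
            raise DegenerateInputError("scores must be integers 1–5")
        readers = self.scores["reader"].unique()
        if len(readers) != 2:
            raise DegenerateInputError(f"expected exactly 2 readers, got {len(readers)}")

    def reader_pairs(self, criterion: str | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Aligned score vectors (reader1, reader2), optionally per criterion."""
        df = self.scores
        if criterion is not None:
            df = df[df["criterion"] == criterion]
        r1, r2 = sorted(df["reader"].unique())
        keys = [c for c in ("case_id", "criterion", "variant") if c in df.columns]
        wide = df.pivot_table(
            index=keys, columns="reader", values="score", aggfunc="first"
        ).dropna()
        return wide[r1].to_numpy(int), wide[r2].to_numpy(int)


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    interpretation: str
    n: int = 0


# ---------------------------------------------------------------------------
# Normality
# ---------------------------------------------------------------------------

def normality_check(x, method: str = "shapiro_wilk") -> tuple[float, float]:
    """(statistic, p) for Shapiro–Wilk or KS against N(sample mean, sample SD)."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise DegenerateInputError("normality check needs n >= 3")
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant input: normality is undefined")
    if method == "shapiro_wilk":
        res = sps.shapiro(x)
        return float(res.statistic), float(res.pvalue)
    if method == "kolmogorov_smirnov":
        res = sps.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
        return float(res.statistic), float(res.pvalue)
    raise DegenerateInputError(f"unknown normality method {method!r}")


# ---------------------------------------------------------------------------
# Paired tests
# ---------------------------------------------------------------------------

def paired_t(sample: PairedSample) -> tuple[float, int, float]:
    """Paired-samples t-test; returns (t, df, two-sided p)."""
    d = sample.differences
    if np.ptp(d) == 0:
        raise DegenerateInputError(
            f"paired sample {sample.label!r}: differences have zero variance"
        )
    res = sps.ttest_rel(sample.values_a, sample.values_b)
    return float(res.statistic), int(d.size - 1), float(res.pvalue)


def _signed_rank_statistic(d: np.ndarray) -> tuple[float, np.ndarray]:
    """(W+ over nonzero differences, midranks of |d|)."""
    d = d[d != 0]
    if d.size == 0:
        raise DegenerateInputError("all differences are zero")
    ranks = sps.rankdata(np.abs(d))
    return float(ranks[d > 0].sum()), ranks


def _exact_wplus_distribution(ranks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Null distribution of W+ by DP over doubled (integer) midranks.

    Equivalent to enumerating all 2^n equally likely sign assignments.
    Returns (support values of W+, probabilities).
    """
    r2 = np.rint(2 * ranks).astype(int)  # midranks are multiples of 1/2
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    probs = counts / counts.sum()
    support = np.arange(total + 1) / 2.0
    keep = probs > 0
    return support[keep], probs[keep]


def wilcoxon_signed_rank(
    sample: PairedSample,
    alternative: str = "two-sided",
    exact_threshold: int = 15,
) -> tuple[float, float]:
    """Wilcoxon signed-rank test; returns (W+, p).

    Zero differences are dropped and ties mid-ranked.  The p-value is exact
    (sign-assignment enumeration) for n <= ``exact_threshold``, otherwise a
    tie-corrected normal approximation with continuity correction.
    Two-sided p is ``min(1, 2*min(P(W<=w), P(W>=w)))``.
    """
    d = sample.differences
    w_plus, ranks = _signed_rank_statistic(d)
    n = ranks.size
    if n <= exact_threshold:
        support, probs = _exact_wplus_distribution(ranks)
        p_le = float(probs[support <= w_plus + 1e-9].sum())
        p_ge = float(probs[support >= w_plus - 1e-9].sum())
        if alternative == "greater":
            p = p_ge
        elif alternative == "less":
            p = p_le
        else:
            p = min(1.0, 2.0 * min(p_le, p_ge))
        return w_plus, p
    # normal approximation with tie correction
    mu = n * (n + 1) / 4.0
    tie_counts = np.unique(np.rint(2 * ranks).astype(int), return_counts=True)[1]
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - float(
        ((tie_counts**3 - tie_counts) / 48.0).sum()
    )
    if sigma2 <= 0:
        raise DegenerateInputError("signed-rank variance is zero (all ties)")
    sigma = np.sqrt(sigma2)
    if alternative == "greater":
        z = (w_plus - mu - 0.5) / sigma
        p = float(sps.norm.sf(z))
    elif alternative == "less":
        z = (w_plus - mu + 0.5) / sigma
        p = float(sps.norm.cdf(z))
    else:
        z = (abs(w_plus - mu) - 0.5) / sigma
        p = float(2 * sps.norm.sf(z))
    return w_plus, min(1.0, p)


# ---------------------------------------------------------------------------
# Agreement
# ---------------------------------------------------------------------------

KAPPA_BINS = (
    (0.81, "excellent"),
    (0.61, "substantial"),
    (0.41, "moderate"),
    (0.21, "fair"),
)


def interpret_kappa(kappa: float) -> str:
    if not -1.0 - 1e-12 <= kappa <= 1.0 + 1e-12:
        raise DegenerateInputError(f"kappa must lie in [-1, 1], got {kappa}")
    for lo, name in KAPPA_BINS:
        if kappa >= lo - 1e-12:
            return name
    return "poor"


def cohen_kappa(
    ratings: RatingTable,
    criterion: str | None = None,
    weights: str | None = None,
) -> KappaResult:
    """Chance-corrected agreement between the two readers.

    Unweighted by default; ``weights`` in {"linear", "quadratic"} selects
    weighted kappa.  Computed over observed categories; if both readers
    used only a single category the statistic is undefined.
    """
    from sklearn.metrics import cohen_kappa_score

    r1, r2 = ratings.reader_pairs(criterion)
    if r1.size < 2:
        raise DegenerateInputError("kappa needs at least 2 rated cases")
    if len(np.union1d(r1, r2)) < 2:
        raise DegenerateInputError(
            "kappa undefined: both readers used a single category"
        )
    k = float(cohen_kappa_score(r1, r2, weights=weights))
    return KappaResult(kappa=k, interpretation=interpret_kappa(k), n=int(r1.size))


# ---------------------------------------------------------------------------
# Report generation
# ---------------------------------------------------------------------------

METRICS = ("attenuation_hu", "noise_hu", "snr", "cnr", "fwhm_mm")


def _route_and_test(sample: PairedSample, metric: str) -> tuple[str, float]:
    if metric in ALWAYS_WILCOXON:
        _, p = wilcoxon_signed_rank(sample)
        return "wilcoxon", p
    try:
        _, p_norm = normality_check(sample.differences, "shapiro_wilk")
    except DegenerateInputError:
        p_norm = 0.0
    if p_norm >= 0.05:
        try:
            _, _, p = paired_t(sample)
            return "paired_t", p
        except DegenerateInputError:
            pass
    _, p = wilcoxon_signed_rank(sample)
    return "wilcoxon", p


def compare_report(
    qa_records: pd.DataFrame,
    ratings: RatingTable | None = None,
) -> dict[str, pd.DataFrame]:
    """Build the per-segment comparison tables and subjective summary.

    ``qa_records`` is the long table from
    :func:`ceboost.qa.records_to_dataframe` with an added ``case`` column
    identifying the paired unit (patient or phantom seed).  Returns a dict
    of DataFrames: ``objective`` (per segment and metric: mean ± SD per
    variant and the routed two-sided p) and, when ratings are supplied,
    ``agreement`` (per-criterion kappa with interpretation).
    """
    df = qa_records.copy()
    if "case" not in df.columns:
        raise DegenerateInputError("qa_records needs a 'case' column pairing variants")
    # every (case, segment) needs both variant rows; a missing row is a
    # schema error (a missing *value*, e.g. an undefined FWHM, is not —
    # those pairs are dropped per metric)
    variant_sets = df.groupby(["case", "segment"])["variant"].agg(set)
    incomplete = variant_sets[
        variant_sets.apply(lambda s: s != {"conventional", "boosted"})
    ]
    if len(incomplete):
        raise DegenerateInputError(
            f"unpaired QA records for {list(incomplete.index[:5])}"
        )
    rows = []
    for metric in METRICS:
        if metric not in df.columns:
            continue
        for segment, seg_df in df.groupby("segment", sort=False):
            wide = seg_df.pivot_table(
                index="case", columns="variant", values=metric
            ).dropna()
            if not {"conventional", "boosted"} <= set(wide.columns):
                raise DegenerateInputError(
                    f"segment {segment!r}/{metric}: unpaired records"
                )
            conv = wide["conventional"].to_numpy(float)
            boost = wide["boosted"].to_numpy(float)
            sample = PairedSample(boost, conv, label=f"{segment}:{metric}")
            test, p = _route_and_test(sample, metric)
            rows.append(
                {
                    "metric": metric,
                    "segment": segment,
                    "n": conv.size,
                    "conventional_mean": conv.mean(),
                    "conventional_sd": conv.std(ddof=1),
                    "boosted_mean": boost.mean(),
                    "boosted_sd": boost.std(ddof=1),
                    "test": test,
                    "p_value": p,
                }
            )
        # pooled average across segments, one value per case
        pooled = (
            df.pivot_table(index=["case", "variant"], values=metric)
            .reset_index()
            .pivot_table(index="case", columns="variant", values=metric)
            .dropna()
        )
        conv = pooled["conventional"].to_numpy(float)
        boost = pooled["boosted"].to_numpy(float)
        sample = PairedSample(boost, conv, label=f"average:{metric}")
        test, p = _route_and_test(sample, metric)
        rows.append(
            {
                "metric": metric,
                "segment": "average",
                "n": conv.size,
                "conventional_mean": conv.mean(),
                "conventional_sd": conv.std(ddof=1),
                "boosted_mean": boost.mean(),
                "boosted_sd": boost.std(ddof=1),
                "test": test,
                "p_value": p,
            }
        )
    out: dict[str, pd.DataFrame] = {"objective": pd.DataFrame(rows)}

    if ratings is not None:
        agree_rows = []
        for criterion in ratings.scores["criterion"].unique():
            res = cohen_kappa(ratings, criterion=criterion)
            agree_rows.append(
                {
                    "criterion": criterion,
                    "n": res.n,
                    "kappa": res.kappa,
                    "interpretation": res.interpretation,
                }
            )
        pooled_res = cohen_kappa(ratings)
        agree_rows.append(
            {
                "criterion": "all (pooled)",
                "n": pooled_res.n,
                "kappa": pooled_res.kappa,
                "interpretation": pooled_res.interpretation,
            }
        )
        out["agreement"] = pd.DataFrame(agree_rows)
    return out


def report_to_markdown(tables: dict[str, pd.DataFrame]) -> str:
    parts = []
    for name, table in tables.items():
        parts.append(f"## {name}\n")
        parts.append(table.to_markdown(index=False))
        parts.append("")
    return "\n".join(parts)
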