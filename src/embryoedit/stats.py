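"""Cohort-level editing efficiencies and proportion tests.

Two denominator conventions for knockout-generation efficiency are in use
for embryo cohorts, so both are reported: ``ko_of_edited_pct`` (KO embryos
over edited embryos) and ``ko_of_total_pct`` (KO embryos over all genotyped
embryos).
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats as sps


@dataclass(frozen=True)
class CohortSummary:
    n_genotyped: int
    n_wt: int
    n_if: int
    n_hz: int
    n_ko: int
    n_no_call: int

    @property
    def n_edited(self) -> int:
        return self.n_genotyped - self.n_wt

    @property
    def edit_efficiency_pct(self) -> float:
        return 100.0 * self.n_edited / self.n_genotyped

    @property
    def ko_of_edited_pct(self) -> float | None:
        """KO percentage among edited embryos; None when nothing is edited."""
        if self.n_edited == 0:
            return None
        return 100.0 * self.n_ko / self.n_edited

    @property
    def ko_of_total_pct(self) -> float:
        return 100.0 * self.n_ko / self.n_genotyped

    def as_dict(self) -> dict:
        ko_edited = self.ko_of_edited_pct
        return {
            "n_genotyped": self.n_genotyped,
            "n_wt": self.n_wt,
            "n_if": self.n_if,
            "n_hz": self.n_hz,
            "n_ko": self.n_ko,
            "n_edited": self.n_edited,
            "n_no_call": self.n_no_call,
            "edit_efficiency_pct": round(self.edit_efficiency_pct, 1),
            "ko_of_edited_pct": None if ko_edited is None else round(ko_edited, 1),
            "ko_of_total_pct": round(self.ko_of_total_pct, 1),
        }


def summarize(calls: list[str]) -> CohortSummary:
    """Count embryo genotype calls; no-calls are excluded from the denominator
    but their count is reported."""
    if not calls:
        raise ValueError("no genotypes to summarize")
    n_no_call = sum(c == "no-call" for c in calls)
    kept = [c for c in calls if c != "no-call"]
    if not kept:
        raise ValueError("all embryos are no-calls")
    counts = {k: sum(c == k for c in kept) for k in ("WT", "IF", "Hz", "KO")}
    unknown = set(kept) - {"WT", "IF", "Hz", "KO"}
    if unknown:
        raise ValueError(f"unknown genotype calls {unknown}")
    return CohortSummary(
        n_genotyped=len(kept),
        n_wt=counts["WT"],
        n_if=counts["IF"],
        n_hz=counts["Hz"],
        n_ko=counts["KO"],
        n_no_call=n_no_call,
    )


def compare_proportions(
    k1: int, n1: int, k2: int, n2: int, continuity: bool = False
) -> tuple[float, float, str]:
    """Two-sided comparison of two proportions k1/n1 vs k2/n2.

    Uses Pearson's chi-squared test (without continuity correction unless
    ``continuity`` is set) when all expected counts are >= 5, otherwise
    Fisher's exact test. Returns ``(statistic, p_value, method)``; the
    statistic is NaN for Fisher (its odds ratio is not a test statistic).
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n <= 0 or k < 0 or k > n:
            raise ValueError(f"invalid counts k={k}, n={n}")
    table = [[k1, n1 - k1], [k2, n2 - k2]]
    total = n1 + n2
    col1, col2 = k1 + k2, (n1 - k1) + (n2 - k2)
    expected = [
        n1 * col1 / total, n1 * col2 / total,
        n2 * col1 / total, n2 * col2 / total,
    ]
    if min(expected) >= 5:
        stat, p, _, _ = sps.chi2_contingency(table, correction=continuity)
        return float(stat), float(p), "chi2"
    _, p = sps.fisher_exact(table, alternative="two-sided")
    return float("nan"), float(p), "fisher"
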