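"""Method-agreement and breed-comparison statistics.

Two methods measure the same bodyweight: the scale ("measured") and the
CT pipeline ("CT-derived", the sum of bone, lean and fat tissue weights).
Bland-Altman limits of agreement summarise their paired differences
(derived - measured): mean difference d, sample SD s, limits d +/- 1.96 s.
The accompanying p-value is a two-sided one-sample t-test of the
differences against zero — the conventional companion test for a mean
paired difference.

Lean:fat ratios are compared between breeds with an exact two-sided
Mann-Whitney U test: U is computed from midranks, and the exact p-value
enumerates all C(n+m, n) assignments of the pooled values to groups
(2 x the smaller tail probability, capped at 1). For larger groups the
normal approximation with tie correction is used and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from itertools import combinations
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger("ctcomp")

#: Largest per-group size for which the exact enumeration is used.
EXACT_LIMIT = 10


@dataclass
class AnimalRecord:
    """One animal on one study day: identity, measured BW, tissue masses."""

    id: str
    breed: str
    day: int
    bone_kg: float
    lean_kg: float
    fat_kg: float
    measured_bw_kg: float | None = None

    def __post_init__(self) -> None:
        if self.measured_bw_kg is not None and self.measured_bw_kg <= 0:
            raise ValueError(f"{self.id}: measured bodyweight must be > 0")

    @property
    def ct_derived_bw_kg(self) -> float:
        return self.bone_kg + self.lean_kg + self.fat_kg

    @property
    def lean_fat_ratio(self) -> float:
        return self.lean_kg / self.fat_kg


@dataclass(frozen=True)
class AgreementResult:
    """Bland-Altman limits of agreement for paired measurements (kg)."""

    mean_difference: float
    sd_difference: float
    ba_lower: float
    ba_upper: float
    ba_range: float  # signed: lower - upper = -3.92 * sd
    p_value: float
    n: int


@dataclass(frozen=True)
class MannWhitneyResult:
    """Mann-Whitney U (first group) with its two-sided p-value."""

    u: float
    p_value: float
    n1: int
    n2: int
    method: str  # "exact" | "asymptotic"


# ---------------------------------------------------------------------------
# Bland-Altman
# ---------------------------------------------------------------------------


def bland_altman(measured, derived) -> AgreementResult:
    """Limits of agreement between measured and derived values.

    Differences are derived - measured, so a method that underestimates
    yields a negative mean difference. Requires at least two pairs.
    """
    measured = np.asarray(measured, dtype=float)
    derived = np.asarray(derived, dtype=float)
    if measured.shape != derived.shape:
        raise ValueError(f"length mismatch: {measured.shape} vs {derived.shape}")
    n = measured.size
    if n < 2:
        raise ValueError("at least 2 paired observations are required")
    diffs = derived - measured
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    lower = mean - 1.96 * sd
    upper = mean + 1.96 * sd
    if sd == 0:
        p = float("nan") if mean == 0 else 0.0
    else:
        p = float(sps.ttest_1samp(diffs, 0.0).pvalue)
    return AgreementResult(
        mean_difference=mean,
        sd_difference=sd,
        ba_lower=float(lower),
        ba_upper=float(upper),
        ba_range=float(lower - upper),
        p_value=p,
        n=n,
    )


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------


def _u_from_ranks(ranks: np.ndarray, n1: int) -> float:
    return float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)


def mann_whitney_exact(a, b) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test; exact by enumeration for small groups.

    Ties receive midranks, and the exact null distribution enumerates
    group assignments of the pooled multiset, so tied data are handled
    exactly. The exact route is used when both groups have at most
    ``EXACT_LIMIT`` observations; otherwise the tie-corrected normal
    approximation is used (logged).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u_obs = _u_from_ranks(ranks, n1)

    if n1 <= EXACT_LIMIT and n2 <= EXACT_LIMIT:
        total = comb(n1 + n2, n1)
        eps = 1e-9
        n_le = n_ge = 0
        for idx in combinations(range(n1 + n2), n1):
            u = float(ranks[list(idx)].sum()) - n1 * (n1 + 1) / 2.0
            if u <= u_obs + eps:
                n_le += 1
            if u >= u_obs - eps:
                n_ge += 1
        p = min(1.0, 2.0 * min(n_le, n_ge) / total)
        return MannWhitneyResult(u=u_obs, p_value=p, n1=n1, n2=n2, method="exact")

    logger.info(
        "mann_whitney_exact: group sizes %d, %d exceed exact limit %d; "
        "using tie-corrected normal approximation", n1, n2, EXACT_LIMIT,
    )
    N = n1 + n2
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / (N * (N - 1))
    sigma2 = n1 * n2 / 12.0 * ((N + 1) - tie_term)
    if sigma2 <= 0:
        return MannWhitneyResult(u=u_obs, p_value=1.0, n1=n1, n2=n2, method="asymptotic")
    z = (u_obs - mu) / np.sqrt(sigma2)
    p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return MannWhitneyResult(u=u_obs, p_value=p, n1=n1, n2=n2, method="asymptotic")


# ---------------------------------------------------------------------------
# Group summaries
# ---------------------------------------------------------------------------


def summarize_groups(records: list[AnimalRecord]) -> pd.DataFrame:
    """Mean and sample SD per (breed, day) of masses, BW and lean:fat ratio.

    Means and SDs are unrounded; rendering rounds separately. Ratios are
    averaged over the per-animal (unrounded) ratios. A group with a single
    animal reports its SD as missing.
    """
    if not records:
        raise ValueError("no records to summarise")
    frame = pd.DataFrame(
        {
            "breed": [r.breed for r in records],
            "day": [r.day for r in records],
            "bone_kg": [r.bone_kg for r in records],
            "lean_kg": [r.lean_kg for r in records],
            "fat_kg": [r.fat_kg for r in records],
            "ct_derived_bw_kg": [r.ct_derived_bw_kg for r in records],
            "lean_fat_ratio": [r.lean_fat_ratio for r in records],
            "measured_bw_kg": [
                r.measured_bw_kg if r.measured_bw_kg is not None else np.nan for r in records
            ],
        }
    )
    grouped = frame.groupby(["breed", "day"])
    out = grouped.agg(["mean", "std", "count"])
    out.columns = [f"{col}_{stat}" for col, stat in out.columns]
    return out.reset_index()


def breed_ratio_test(records: list[AnimalRecord], day: int) -> MannWhitneyResult:
    """Exact Mann-Whitney on lean:fat ratios between the two breeds on a day."""
    sub = [r for r in records if r.day == day]
    breeds = sorted({r.breed for r in sub})
    if len(breeds) != 2:
        raise ValueError(f"expected exactly 2 breeds on day {day}, found {breeds}")
    a = [r.lean_fat_ratio for r in sub if r.breed == breeds[0]]
    b = [r.lean_fat_ratio for r in sub if r.breed == breeds[1]]
    return mann_whitney_exact(a, b)


def group_agreement(records: list[AnimalRecord]) -> dict[tuple[str, int], AgreementResult]:
    """Bland-Altman of measured vs CT-derived BW per (breed, day) group.

    Groups lacking measured bodyweights are skipped with a log note.
    """
    out: dict[tuple[str, int], AgreementResult] = {}
    keys = sorted({(r.breed, r.day) for r in records})
    for key in keys:
        group = [r for r in records if (r.breed, r.day) == key]
        if any(r.measured_bw_kg is None for r in group):
            logger.info("group %s lacks measured bodyweights; agreement skipped", key)
            continue
        if len(group) < 2:
            logger.info("group %s has a single animal; agreement skipped", key)
            continue
        measured = [r.measured_bw_kg for r in group]
        derived = [r.ct_derived_bw_kg for r in group]
        out[key] = bland_altman(measured, derived)
    return out


def pooled_agreement(records: list[AnimalRecord]) -> AgreementResult | None:
    """Bland-Altman over every animal with a measured bodyweight, all groups
    pooled; None when fewer than two measured animals exist."""
    measured = [r.measured_bw_kg for r in records if r.measured_bw_kg is not None]
    derived = [r.ct_derived_bw_kg for r in records if r.measured_bw_kg is not None]
    if len(measured) < 2:
        return None
    return bland_altman(measured, derived)


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------


def read_animal_table(path: str | Path) -> list[AnimalRecord]:
    """Read animal records from tab-delimited text.

    Required columns: id, breed, day, bone_kg, lean_kg, fat_kg; optional:
    measured_bw_kg.
    """
    frame = pd.read_csv(path, sep="\t", comment="#")
    required = {"id", "breed", "day", "bone_kg", "lean_kg", "fat_kg"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for _, row in frame.iterrows():
        bw = row.get("measured_bw_kg")
        records.append(
            AnimalRecord(
                id=str(row["id"]),
                breed=str(row["breed"]),
                day=int(row["day"]),
                bone_kg=float(row["bone_kg"]),
                lean_kg=float(row["lean_kg"]),
                fat_kg=float(row["fat_kg"]),
                measured_bw_kg=float(bw) if bw is not None and pd.notna(bw) else None,
            )
        )
    return records


def load_reference_composition() -> list[AnimalRecord]:
    """Bundled reference dataset: 12 dogs (6 beagles, 6 greyhounds), whole-body
    CT composition on study days 0 and 28."""
    path = resources.files("ctcomp").joinpath("data/dog_body_composition.tsv")
    with resources.as_file(path) as p:
        return read_animal_table(p)


def write_summary_report(path: str | Path, records: list[AnimalRecord], ndigits: int = 1) -> None:
    """Write a group-summary + breed-comparison report as delimited text."""
    from .composition import round_half_away

    summary = summarize_groups(records)
    lines = ["# group summaries (mean, sample SD, n)"]
    lines.append("\t".join(summary.columns.astype(str)))
    for _, row in summary.iterrows():
        cells = []
        for col in summary.columns:
            v = row[col]
            if isinstance(v, float):
                cells.append("NA" if np.isnan(v) else f"{round_half_away(v, ndigits):.{ndigits}f}")
            else:
                cells.append(str(v))
        lines.append("\t".join(cells))
    days = sorted({r.day for r in records})
    lines.append("")
    lines.append("# breed comparison of lean:fat ratio (Mann-Whitney)")
    lines.append("day\tU\tp_value\tmethod\tn1\tn2")
    for day in days:
        try:
            res = breed_ratio_test(records, day)
        except ValueError:
            continue
        lines.append(f"{day}\t{res.u:g}\t{res.p_value:.6g}\t{res.method}\t{res.n1}\t{res.n2}")
    rows: list[tuple[str, str, AgreementResult]] = []
    pooled = pooled_agreement(records)
    if pooled is not None:
        rows.append(("all", "all", pooled))
    rows.extend((breed, str(day), res) for (breed, day), res in group_agreement(records).items())
    if rows:
        lines.append("")
        lines.append("# bodyweight agreement, derived - measured (Bland-Altman)")
        lines.append("breed\tday\tn\tmean_diff_kg\tsd_diff_kg\tba_lower_kg\tba_upper_kg\tba_range_kg\tp_value")
        for breed, day, res in rows:
            lines.append(
                f"{breed}\t{day}\t{res.n}\t{res.mean_difference:.4f}\t{res.sd_difference:.4f}"
                f"\t{res.ba_lower:.4f}\t{res.ba_upper:.4f}\t{res.ba_range:.4f}\t{res.p_value:.6g}"
            )
    Path(path).write_text("\n".join(lines) + "\n")
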