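"""Adaptation-mode tallies and contingency tests across ploidies.

Per-case assignments (gene x quartet of two lineage-distinct population
contrasts) name the most likely evolutionary source of the selected allele
-- de novo mutation, standing variation or migration -- together with the
most likely selection coefficient (maxSel) from a fixed bin set.  Neutral
cases are excluded from all tallies.  Ploidy contrasts use the 2x2
chi-square with Yates continuity correction and Fisher's exact test.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

MODES = ("denovo", "standing", "migration")
MAXSEL_BINS = (0.0001, 0.001, 0.01, 0.05, 0.5)

MODE_COLUMNS = ["gene_id", "quartet_id", "ploidy", "mode", "maxSel", "mcl"]


def read_mode_cases(path) -> pd.DataFrame:
    cases = pd.read_csv(path, sep="\t")
    missing = [c for c in MODE_COLUMNS[:5] if c not in cases.columns]
    if missing:
        raise ValueError(f"mode table lacks columns: {missing}")
    bad = ~cases["mode"].isin(MODES + ("neutral",))
    if bad.any():
        raise ValueError(f"unknown modes: {cases.loc[bad, 'mode'].unique().tolist()}")
    binned = ~cases["maxSel"].isin(MAXSEL_BINS)
    if binned.any():
        raise ValueError("maxSel values outside the fixed bin set")
    return cases


def enumerate_quartets(contrasts: list) -> list:
    """All unordered pairs of lineage-distinct contrasts.

    ``contrasts`` is a list of (contrast_id, lineage); call per ploidy.
    Six lineage-distinct contrasts yield 15 quartets, four yield 6."""
    if len(contrasts) < 2:
        logger.warning("fewer than 2 contrasts: no quartets")
        return []
    return [
        (a[0], b[0])
        for a, b in combinations(contrasts, 2)
        if a[1] != b[1]
    ]


def tally_modes(cases: pd.DataFrame) -> pd.DataFrame:
    """Counts and fractions per mode per ploidy (non-neutral cases only)."""
    nn = cases[cases["mode"] != "neutral"]
    rows = []
    for ploidy in sorted(nn["ploidy"].unique()):
        sub = nn[nn["ploidy"] == ploidy]
        total = len(sub)
        for mode in MODES:
            n = int((sub["mode"] == mode).sum())
            rows.append((int(ploidy), mode, n, n / total if total else 0.0))
    return pd.DataFrame(rows, columns=["ploidy", "mode", "n", "fraction"])


def yates_chisq(table) -> dict:
    """2x2 chi-square with Yates continuity correction.

    statistic = N(|ad - bc| - N/2)^2 / ((a+b)(c+d)(a+c)(b+d)), with the
    corrected term clamped at 0 when |ad - bc| < N/2; p from chi-square
    with 1 degree of freedom."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("need a 2x2 table of non-negative integers")
    a, b = t[0]
    c, d = t[1]
    n = t.sum()
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        raise ValueError(f"zero margin in table {t.tolist()}")
    corrected = max(abs(a * d - b * c) - n / 2.0, 0.0)
    stat = n * corrected**2 / margins
    return {"statistic": float(stat), "df": 1, "p": float(sps.chi2.sf(stat, 1))}


def fisher_exact(table, two_tailed: bool = True) -> float:
    """Fisher's exact test on a 2x2 table (two-tailed by default)."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative integers")
    if (t.sum(axis=1) == 0).any() or (t.sum(axis=0) == 0).any():
        raise ValueError(f"empty row or column in table {t.tolist()}")
    alternative = "two-sided" if two_tailed else "greater"
    return float(sps.fisher_exact(t.astype(int), alternative=alternative)[1])


def mode_contingency_tests(cases: pd.DataFrame) -> pd.DataFrame:
    """Per-mode 2x2 ploidy comparison (mode vs rest), Yates chi-square and
    Fisher exact, on non-neutral cases."""
    nn = cases[cases["mode"] != "neutral"]
    ploidies = sorted(nn["ploidy"].unique())
    if len(ploidies) != 2:
        raise ValueError("need cases from exactly two ploidies")
    rows = []
    for mode in MODES:
        cells = []
        for ploidy in ploidies:
            sub = nn[nn["ploidy"] == ploidy]
            k = int((sub["mode"] == mode).sum())
            cells.append([k, len(sub) - k])
        col_sums = np.asarray(cells).sum(axis=0)
        if (col_sums == 0).any():  # mode absent (or universal) in both ploidies
            logger.warning("mode %s: degenerate table %s, tests undefined", mode, cells)
            chi = {"statistic": float("nan"), "p": float("nan")}
            fish = float("nan")
        else:
            chi = yates_chisq(cells)
            fish = fisher_exact(cells)
        rows.append(
            (
                mode,
                cells[0][0], cells[0][1], cells[1][0], cells[1][1],
                chi["statistic"], chi["p"], fish,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["mode", "a", "b", "c", "d", "chisq", "chisq_p", "fisher_p"],
    )


def bin_selection_strength(cases: pd.DataFrame) -> dict:
    """Per-ploidy maxSel bin proportions (all bins reported, absent ones as
    zero) plus per-bin Fisher tests of ploidy x (bin vs rest)."""
    nn = cases[cases["mode"] != "neutral"]
    if not nn["maxSel"].isin(MAXSEL_BINS).all():
        raise ValueError("maxSel values outside the fixed bin set")
    ploidies = sorted(nn["ploidy"].unique())
    prop_rows = []
    for ploidy in ploidies:
        sub = nn[nn["ploidy"] == ploidy]
        total = len(sub)
        for b in MAXSEL_BINS:
            k = int((sub["maxSel"] == b).sum())
            prop_rows.append((int(ploidy), b, k, k / total if total else 0.0))
    proportions = pd.DataFrame(prop_rows, columns=["ploidy", "maxSel", "n", "fraction"])

    tests = []
    if len(ploidies) == 2:
        for b in MAXSEL_BINS:
            cells = []
            degenerate = False
            for ploidy in ploidies:
                sub = nn[nn["ploidy"] == ploidy]
                k = int((sub["maxSel"] == b).sum())
                cells.append([k, len(sub) - k])
            col_sums = np.asarray(cells).sum(axis=0)
            if (col_sums == 0).any():
                degenerate = True
            tests.append((b, float("nan") if degenerate else fisher_exact(cells)))
    tests_df = pd.DataFrame(tests, columns=["maxSel", "fisher_p"])
    return {"proportions": proportions, "tests": tests_df}
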