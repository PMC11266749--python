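"""Screen classification (Groups I/II/III), tallies and the sterility test.

Classification of one transcript from its per-stage annotations:

* foci in at least one P blastomere and a PGC-maintenance pattern
  (one enriched cell at the ~40/60-cell stages, two at ~100 cells) -> Group I;
* foci but no PGC pattern -> Group II;
* no foci in any P blastomere -> Group III, regardless of PGC pattern
  (a handful of foci-negative transcripts still show the maintenance
  pattern).

The sterility comparison is Fisher's exact test on a 2x2 table, computed
from first principles by summing hypergeometric probabilities no larger
than that of the observed table (exact rational arithmetic, so ties are
handled without floating-point fuzz).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .imaging_io import round_half_up

log = logging.getLogger("granulefish")

__all__ = [
    "GROUP_I",
    "GROUP_II",
    "GROUP_III",
    "classify_transcript",
    "classify_table",
    "tally_screen",
    "ScreenTally",
    "fisher_exact",
    "unpaired_t_test",
]

GROUP_I = "I"
GROUP_II = "II"
GROUP_III = "III"

_FOCI_COLUMNS = ["foci_P1", "foci_P2", "foci_P3", "foci_P4"]


def classify_transcript(foci_flags, pgc_pattern: bool) -> str:
    """Assign a transcript's group from its boolean annotations.

    ``foci_flags`` is a sequence or mapping of the four per-stage foci
    booleans (P1-P4).
    """
    if hasattr(foci_flags, "get"):
        flags = [bool(foci_flags[c]) for c in _FOCI_COLUMNS]
    else:
        flags = [bool(f) for f in foci_flags]
    if len(flags) != 4:
        raise ValueError("expected four per-stage foci flags (P1-P4)")
    if any(flags):
        return GROUP_I if pgc_pattern else GROUP_II
    return GROUP_III


def classify_table(table: pd.DataFrame) -> pd.DataFrame:
    """Derive (or re-derive) the ``group`` column of a screen table."""
    out = table.copy()
    out["group"] = [
        classify_transcript(
            [row[c] for c in _FOCI_COLUMNS], bool(row["pgc_pattern"])
        )
        for _, row in out.iterrows()
    ]
    return out


@dataclass
class ScreenTally:
    """Screen-wide counts with both exact and report (half-up integer)
    percentages."""

    n_total: int
    n_foci_positive: int
    n_group_i: int
    n_group_ii: int
    n_group_iii: int
    pct_foci_positive: float
    pct_group_i_of_foci: float
    pct_group_ii_of_foci: float
    pct_group_iii_of_all: float

    @property
    def report(self) -> dict[str, int]:
        return {
            "pct_foci_positive": round_half_up(self.pct_foci_positive),
            "pct_group_i_of_foci": round_half_up(self.pct_group_i_of_foci),
            "pct_group_ii_of_foci": round_half_up(self.pct_group_ii_of_foci),
            "pct_group_iii_of_all": round_half_up(self.pct_group_iii_of_all),
        }


def tally_screen(table: pd.DataFrame) -> ScreenTally:
    """Tally a classified screen table.

    Foci-positive share (Groups I+II) is reported over all transcripts;
    Group I and II shares over the foci-positive subset; Group III over all.
    """
    if len(table) == 0:
        raise ValueError("empty screen table")
    groups = table["group"].astype(str)
    n_i = int((groups == GROUP_I).sum())
    n_ii = int((groups == GROUP_II).sum())
    n_iii = int((groups == GROUP_III).sum())
    n_total = len(table)
    if n_i + n_ii + n_iii != n_total:
        raise ValueError("group column contains labels other than I/II/III")
    n_foci = n_i + n_ii
    return ScreenTally(
        n_total=n_total,
        n_foci_positive=n_foci,
        n_group_i=n_i,
        n_group_ii=n_ii,
        n_group_iii=n_iii,
        pct_foci_positive=100.0 * n_foci / n_total,
        pct_group_i_of_foci=100.0 * n_i / n_foci if n_foci else 0.0,
        pct_group_ii_of_foci=100.0 * n_ii / n_foci if n_foci else 0.0,
        pct_group_iii_of_all=100.0 * n_iii / n_total,
    )


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def fisher_exact(table) -> float:
    """Two-sided Fisher's exact test p-value for a 2x2 contingency table.

    With fixed margins, sums the probabilities of all tables whose
    hypergeometric probability does not exceed that of the observed table.
    Probabilities are exact rationals, so equal-probability tables are
    included without tolerance games.  Degenerate margins return p = 1 by
    convention.
    """
    t = np.asarray(table, dtype=object)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be >= 0")
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if n == 0 or r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        log.info("degenerate 2x2 margins: returning p = 1")
        return 1.0
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    denom = comb(n, c1)
    probs = {
        k: Fraction(comb(r1, k) * comb(n - r1, c1 - k), denom)
        for k in range(lo, hi + 1)
    }
    p_obs = probs[a]
    p = sum((q for q in probs.values() if q <= p_obs), Fraction(0))
    return float(min(p, Fraction(1)))


def unpaired_t_test(x, y) -> tuple[float, float]:
    """Thin wrapper for the unpaired two-sample t-test; returns (t, p)."""
    res = stats.ttest_ind(np.asarray(x, float), np.asarray(y, float))
    return float(res.statistic), float(res.pvalue)
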