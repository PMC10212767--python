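"""The 2x2 odds-ratio machinery shared by every statistical test in IRIS.

Each enrichment question in the pipeline — is this window antisense-rich, is
this locus expressed, did poly(A)-site usage shift — reduces to a 2x2 table
of read counts.  With one binary predictor the logistic-regression MLE
coefficient equals the sample log odds ratio, so the tests are computed in
closed form: a Haldane-Anscombe pseudocount of 0.5 is added to all four
cells (always, not only on zeros, keeping estimate and standard error
consistent), the log2 odds ratio is the effect size (logASR), and a Wald
z = lnOR / sqrt(sum 1/(cell+c)) gives a two-sided normal p-value.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

_LN2 = np.log(2.0)
_TINY = np.finfo(float).tiny


def _validate_cells(*cells) -> tuple[np.ndarray, ...]:
    arrays = tuple(np.asarray(c, dtype=float) for c in cells)
    for arr in arrays:
        if np.any(arr < 0):
            raise ValueError("counts must be non-negative")
    return arrays


def table_stats(a_w, a_r, s_w, s_r, pseudocount: float = 0.5):
    """Vectorised statistics for 2x2 tables (antisense/sense x window/rest).

    Returns ``(log_asr, ln_or, se, z, p)``; all five broadcast over array
    inputs.  The all-zero table gives z = 0 and hence p = 1 (the stated
    convention falls out of the pseudocount).
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    a_w, a_r, s_w, s_r = _validate_cells(a_w, a_r, s_w, s_r)
    c = float(pseudocount)
    # terms paired per strand so swapping the strands negates lnOR (and
    # leaves the SE) bit-exactly: float addition is commutative
    ln_or = (np.log(a_w + c) - np.log(a_r + c)) + (np.log(s_r + c) - np.log(s_w + c))
    se = np.sqrt(
        (1 / (a_w + c) + 1 / (a_r + c)) + (1 / (s_w + c) + 1 / (s_r + c))
    )
    z = ln_or / se
    p = np.maximum(2.0 * norm.sf(np.abs(z)), _TINY)
    return ln_or / _LN2, ln_or, se, z, p


def log_asr(a_w, a_r, s_w, s_r, pseudocount: float = 0.5):
    """logASR: log2 of the pseudocounted odds ratio

    ((a_w+c)/(a_r+c)) / ((s_w+c)/(s_r+c)).

    Positive values mean the window holds a larger share of the transcript's
    antisense reads than of its sense reads.  Always finite.
    """
    return table_stats(a_w, a_r, s_w, s_r, pseudocount)[0]


def window_test(a_w, a_r, s_w, s_r, pseudocount: float = 0.5):
    """Two-sided Wald p-value for the strand-by-region odds ratio.

    Equivalent to the single-coefficient Wald test of a saturated logistic
    regression of read strand on window membership.
    """
    return table_stats(a_w, a_r, s_w, s_r, pseudocount)[4]


def adjust_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with input."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
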