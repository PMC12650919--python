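"""Bundled example data.

``example_cohort`` returns the pilot cohort of six maxillary sinus
samples (four patients, some bilateral) measured before pterygoid or
zygomatic implant surgery and again 14-16 months after.  Each volume is
the midpoint of the lower/upper interval estimate produced by the
pipeline, with its half-width error.  The cohort is the canonical input
for :func:`sinusvol.agreement.cohort_summary` and the ``cohort`` CLI
command.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["example_cohort"]

_COHORT_ROWS = [
    # sample_id, v_pre, err_pre, v_post, err_post
    ("Sample 1", 19734.1, 1094.5, 19521.9, 1126.5),
    ("Sample 2", 18990.2, 1004.6, 18087.4, 1006.8),
    ("Sample 3", 15959.7, 933.9, 14552.6, 899.6),
    ("Sample 4", 20756.2, 1111.5, 18313.2, 1098.9),
    ("Sample 5", 10525.6, 420.2, 8083.3, 510.9),
    ("Sample 6", 10860.4, 750.4, 8197.4, 430.2),
]


def example_cohort() -> pd.DataFrame:
    """Six paired pre/post sinus volume estimates from a pilot implant cohort."""
    return pd.DataFrame(
        _COHORT_ROWS,
        columns=["sample_id", "v_pre", "err_pre", "v_post", "err_post"],
    )
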