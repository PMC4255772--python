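"""Stability statistics per structural class and the ΣdN–ΔΔG correlation.

ΔΔG values (kJ/mol, predicted stability change upon alanine mutation) are
produced externally and consumed as a table keyed by (chain, residue
number).  Per class × chain groups we report mean, SD and SE, and contrast
all group pairs within a chain with Welch's unequal-variance t-test at the
0.05 and 0.0005 significance tiers.  The evolvability-stability relation is
summarised by the Pearson correlation between per-group ΣdN and mean ΔΔG,
with a leave-one-out re-run to probe single-group leverage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DdgTable",
    "GroupStats",
    "CorrelationResult",
    "read_ddg_tsv",
    "group_ddg_stats",
    "dn_ddg_correlation",
]


@dataclass
class GroupStats:
    chain: str
    site_class: str
    n: int
    mean: float
    sd: float
    se: float
    degenerate: bool = False  # zero within-group variance


@dataclass
class CorrelationResult:
    n: int
    r: float
    p: float
    labels: list

    def excluding(self, label, points) -> "CorrelationResult":
        keep = [(lbl, x, y) for lbl, x, y in points if lbl != label]
        return dn_ddg_correlation(
            [(x, y) for _, x, y in keep], labels=[lbl for lbl, _, _ in keep]
        )


def read_ddg_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chain": str})
    required = {"chain", "resnum", "ddg_kj_mol"}
    if not required <= set(df.columns):
        raise ValueError(f"ΔΔG table needs columns {sorted(required)}")
    if not np.isfinite(df["ddg_kj_mol"]).all():
        raise ValueError("non-finite ΔΔG values")
    return df


DdgTable = pd.DataFrame  # rows: chain, resnum, ddg_kj_mol


def group_ddg_stats(ddg: pd.DataFrame, labels, min_group: int = 2):
    """Per (chain × class) ΔΔG statistics and within-chain Welch contrasts.

    ``labels`` is an iterable of site labels (``chain_id``, ``seq_number``,
    ``site_class``).  Returns ``(stats_list, contrasts_df)``; groups smaller
    than ``min_group`` are omitted with a warning row in the contrasts frame.
    Contrasts carry significance tiers at P < 0.05 (``*``) and P < 0.0005
    (``**``); comparisons against a zero-variance pair of groups are flagged
    degenerate rather than tested.
    """
    lab_map = {}
    for lab in labels:
        cls = getattr(lab.site_class, "value", lab.site_class)
        lab_map[(str(lab.chain_id), int(lab.seq_number))] = cls
    df = ddg.copy()
    df["site_class"] = [
        lab_map.get((str(c), int(r))) for c, r in zip(df["chain"], df["resnum"])
    ]
    df = df.dropna(subset=["site_class"])

    groups = []
    values = {}
    for (chain, cls), sub in df.groupby(["chain", "site_class"], sort=True):
        v = sub["ddg_kj_mol"].to_numpy(dtype=float)
        if len(v) < min_group:
            continue
        sd = float(np.std(v, ddof=1))
        groups.append(
            GroupStats(
                chain=str(chain),
                site_class=str(cls),
                n=len(v),
                mean=float(v.mean()),
                sd=sd,
                se=sd / np.sqrt(len(v)),
                degenerate=sd == 0.0,
            )
        )
        values[(str(chain), str(cls))] = v

    rows = []
    by_chain: dict = {}
    for chain, cls in values:
        by_chain.setdefault(chain, []).append(cls)
    for chain, classes in sorted(by_chain.items()):
        classes = sorted(classes)
        for i, a in enumerate(classes):
            for b in classes[i + 1 :]:
                va, vb = values[(chain, a)], values[(chain, b)]
                degenerate = va.std() == 0 and vb.std() == 0
                if degenerate:
                    p = np.nan
                else:
                    p = float(
                        stats.ttest_ind(va, vb, equal_var=False).pvalue
                    )
                tier = ""
                if np.isfinite(p):
                    tier = "**" if p < 0.0005 else ("*" if p < 0.05 else "")
                rows.append(
                    {
                        "chain": chain,
                        "class_a": a,
                        "class_b": b,
                        "mean_a": float(va.mean()),
                        "mean_b": float(vb.mean()),
                        "p_welch": p,
                        "tier": tier,
                        "degenerate": degenerate,
                    }
                )
    return groups, pd.DataFrame(rows)


def dn_ddg_correlation(points, labels=None) -> CorrelationResult:
    """Pearson correlation of (ΣdN, mean ΔΔG) points.

    Two-sided P from the t distribution with n − 2 df.  Zero variance in
    either coordinate yields an undefined (NaN) r.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (ΣdN, ΔΔG) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(
            n=len(x), r=float("nan"), p=float("nan"),
            labels=list(labels) if labels else [],
        )
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(
        n=len(x), r=float(r), p=float(p), labels=list(labels) if labels else []
    )
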