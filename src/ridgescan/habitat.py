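"""Habitat comparison between inferred populations.

For every (environmental variable, resolution) the values at population-A
samples are compared with population-B samples by a tie-corrected
Kruskal-Wallis test (admixed individuals are summarized descriptively), and
the most significant resolution per variable is reported together with the
list of resolutions surviving a Bonferroni correction over the whole
(variables x resolutions) family.  A per-variable Bonferroni family (over
resolutions only) is reported alongside, since either multiplicity reading is
defensible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["HabitatTestRecord", "kruskal_wallis", "habitat_table"]


@dataclass
class HabitatTestRecord:
    variable: str
    resolution: float
    mean_A: float
    sd_A: float
    mean_B: float
    sd_B: float
    mean_adm: float
    sd_adm: float
    h_stat: float
    p: float
    significant_global: bool
    significant_per_var: bool


def kruskal_wallis(values: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square(g-1) p-value."""
    groups = []
    for lab in pd.unique(labels):
        sel = np.asarray(labels) == lab
        if sel.sum() < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 observations")
        groups.append(np.asarray(values)[sel])
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def habitat_table(env: pd.DataFrame, samples: pd.DataFrame,
                  assignment: np.ndarray, alpha: float = 0.05,
                  three_group: bool = False) -> pd.DataFrame:
    """Per (variable, resolution) A-vs-B comparison table.

    ``env`` is the long table (id, var, res, value); ``assignment`` aligns
    with ``samples`` order.  Group means/SDs are reported per resolution; the
    test uses A vs B only unless ``three_group``.
    """
    lab = pd.Series(np.asarray(assignment, dtype=object),
                    index=samples["id"].to_numpy())
    if (lab == "A").sum() < 2 or (lab == "B").sum() < 2:
        raise ValueError("need at least two individuals in each population")
    rows: list[HabitatTestRecord] = []
    for (var, res), sub in env.groupby(["var", "res"], sort=True):
        v = sub.set_index("id")["value"].loc[lab.index]
        groups = {g: v[lab == g].to_numpy() for g in ("A", "B", "admixed")}
        if three_group and len(groups["admixed"]) >= 2:
            h, p = kruskal_wallis(
                np.concatenate([groups["A"], groups["B"], groups["admixed"]]),
                np.concatenate([np.repeat(g, len(groups[g]))
                                for g in ("A", "B", "admixed")]))
        else:
            h, p = kruskal_wallis(
                np.concatenate([groups["A"], groups["B"]]),
                np.concatenate([np.repeat("A", len(groups["A"])),
                                np.repeat("B", len(groups["B"]))]))
        adm = groups["admixed"]
        rows.append(HabitatTestRecord(
            variable=var, resolution=res,
            mean_A=float(np.nanmean(groups["A"])), sd_A=float(np.nanstd(groups["A"])),
            mean_B=float(np.nanmean(groups["B"])), sd_B=float(np.nanstd(groups["B"])),
            mean_adm=float(np.nanmean(adm)) if len(adm) else np.nan,
            sd_adm=float(np.nanstd(adm)) if len(adm) else np.nan,
            h_stat=h, p=p, significant_global=False, significant_per_var=False,
        ))
    df = pd.DataFrame([r.__dict__ for r in rows])
    n_global = len(df)
    df["significant_global"] = df["p"] < alpha / n_global
    per_var_n = df.groupby("variable")["p"].transform("size")
    df["significant_per_var"] = df["p"] < alpha / per_var_n
    df.attrs["family_size_global"] = n_global
    # per-variable summary mirroring a one-row-per-variable table: best p and
    # the resolutions significant after the global correction
    best = (df.sort_values("p").groupby("variable", sort=False).first()
            .reset_index()[["variable", "resolution", "p"]]
            .rename(columns={"resolution": "best_resolution", "p": "best_p"}))
    sig = (df[df["significant_global"]].groupby("variable")["resolution"]
           .apply(lambda s: ",".join(f"{r:g}" for r in sorted(s))))
    best["significant_resolutions"] = best["variable"].map(sig).fillna("")
    df.attrs["summary"] = best
    return df
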