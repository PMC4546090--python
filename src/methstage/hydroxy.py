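"""5-hydroxymethylcytosine estimation from paired BS / oxBS call tables.

Bisulfite sequencing reads both 5mC and 5hmC as methylated; oxidative
bisulfite sequencing reads only 5mC as methylated. The 5hmC level is
therefore the BS level minus the oxBS level at each site. Per-site
differences are clamped at zero (with the raw difference retained for
diagnostics); pooled compartment estimates use the unclamped difference of
pooled levels by default, because per-site clamping biases a small true
signal upward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CytosineCallTable


@dataclass
class HydroxyProfile:
    """Per-site and pooled 5hmC/5mC estimates for one compartment."""

    sites: pd.DataFrame  # chrom, pos, context, bs_level, oxbs_level, hmc_raw, hmc_level
    pooled_bs: float
    pooled_oxbs: float
    pooled_hmc: float  # unclamped pooled difference (clamped at 0 overall)
    pooled_hmc_clamped: float  # mean of per-site clamped estimates

    @property
    def pooled_mc(self) -> float:
        """True 5mC level (the oxBS level)."""
        return self.pooled_oxbs


def estimate_5hmc(
    bs_table: CytosineCallTable,
    oxbs_table: CytosineCallTable,
    min_coverage: int = 6,
    strict_clamping: bool = False,
) -> HydroxyProfile:
    """Per-site and pooled 5hmC from a BS/oxBS pair.

    Only sites covered at least ``min_coverage`` times in *both* assays are
    used (subtraction is meaningless at sites measured in one assay only).
    With ``strict_clamping`` the pooled estimate is the site-mean of clamped
    per-site values instead of the pooled-level difference.
    """
    bs = bs_table.data[["chrom", "pos", "context", "n_meth", "n_total"]]
    ox = oxbs_table.data[["chrom", "pos", "n_meth", "n_total"]]
    m = bs.merge(ox, on=["chrom", "pos"], suffixes=("_bs", "_ox"))
    m = m[(m["n_total_bs"] >= min_coverage) & (m["n_total_ox"] >= min_coverage)]
    if len(m) == 0:
        raise ValueError("no site covered in both BS and oxBS tables")
    sites = pd.DataFrame(
        {
            "chrom": m["chrom"].to_numpy(),
            "pos": m["pos"].to_numpy(),
            "context": m["context"].to_numpy(),
            "bs_level": (m["n_meth_bs"] / m["n_total_bs"]).to_numpy(),
            "oxbs_level": (m["n_meth_ox"] / m["n_total_ox"]).to_numpy(),
        }
    )
    sites["hmc_raw"] = sites["bs_level"] - sites["oxbs_level"]
    sites["hmc_level"] = np.maximum(sites["hmc_raw"], 0.0)
    pooled_bs = float(m["n_meth_bs"].sum() / m["n_total_bs"].sum())
    pooled_oxbs = float(m["n_meth_ox"].sum() / m["n_total_ox"].sum())
    pooled_hmc_clamped = float(sites["hmc_level"].mean())
    pooled_hmc = pooled_hmc_clamped if strict_clamping else max(pooled_bs - pooled_oxbs, 0.0)
    return HydroxyProfile(
        sites=sites,
        pooled_bs=pooled_bs,
        pooled_oxbs=pooled_oxbs,
        pooled_hmc=pooled_hmc,
        pooled_hmc_clamped=pooled_hmc_clamped,
    )


def modified_base_density(
    profile: HydroxyProfile, region_length: int
) -> dict[str, float]:
    """Modified bases per 100 bp for 5hmC and 5mC in a compartment.

    The expected number of modified bases is the sum of per-site levels;
    density = sum / region_length * 100. A compartment can rank differently
    by density than by level when its cytosine density differs (satellite
    repeats are CG-dense, so a moderate level still yields a high density).
    """
    if region_length <= 0:
        raise ValueError("region_length must be positive")
    hmc_sum = float(np.maximum(profile.sites["hmc_raw"], 0.0).sum())
    mc_sum = float(profile.sites["oxbs_level"].sum())
    return {
        "hmc_per_100bp": hmc_sum / region_length * 100.0,
        "mc_per_100bp": mc_sum / region_length * 100.0,
    }


def hmc_context_split(profile: HydroxyProfile) -> dict[str, float]:
    """Fractions of total 5hmC signal at CG vs CH sites."""
    sites = profile.sites
    if len(sites) == 0:
        raise ValueError("empty hydroxymethylation profile")
    hmc = np.maximum(sites["hmc_raw"].to_numpy(), 0.0)
    is_cg = (sites["context"] == "CG").to_numpy()
    total = hmc.sum()
    if total == 0:
        return {"cg_fraction": float("nan"), "ch_fraction": float("nan"),
                "cg_total": 0.0, "ch_total": 0.0}
    cg_total = float(hmc[is_cg].sum())
    ch_total = float(hmc[~is_cg].sum())
    return {
        "cg_fraction": cg_total / total,
        "ch_fraction": ch_total / total,
        "cg_total": cg_total,
        "ch_total": ch_total,
    }
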