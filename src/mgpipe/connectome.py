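"""APL-hub connectivity analysis on synapse tables.

Given a synapse table (one row per annotated synaptic connection) and a
neuron metadata table, the module restricts rows to the calyx region,
tallies per-neuron reciprocal weights with the APL hub, correlates the two
directions, and summarizes compartment localization (bouton fractions for
PNs, claw fractions for KCs, with a KC-subtype comparison).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_formats import SynapseTable

log = logging.getLogger("mgpipe.connectome")

__all__ = [
    "CorrelationResult",
    "FractionSummary",
    "filter_region",
    "reciprocal_weights",
    "weight_correlation",
    "compartment_fractions",
    "subtype_localization_compare",
]


def filter_region(table: SynapseTable, region_label: str) -> SynapseTable:
    """Keep rows whose region label matches exactly; counts are logged and
    an empty result is returned (with a warning) rather than raised."""
    kept = table.df[table.df["region_label"] == region_label]
    log.info("filter_region(%r): kept %d / %d rows", region_label, len(kept),
             len(table.df))
    if kept.empty:
        log.warning("filter_region(%r): no rows retained", region_label)
    out = SynapseTable(df=kept.reset_index(drop=True),
                       coordinate_units=table.coordinate_units)
    out.normalization_log = dict(table.normalization_log,
                                 region_filtered_out=len(table.df) - len(kept))
    return out


def reciprocal_weights(
    table: SynapseTable,
    hub_id: int,
    metadata: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per partner neuron, synapse counts in both directions with the hub.

    ``w_to_apl`` counts rows (pre = neuron, post = hub); ``w_from_apl``
    counts rows (pre = hub, post = neuron).  ``interacting`` marks neurons
    with synapses both made and received.  Neuron class/subtype come from
    ``metadata`` (columns ``neuron_id, cell_class, kc_subtype``); partners
    absent from it are classed ``"other"`` (logged).
    """
    df = table.df
    to_hub = df[df["post_id"] == hub_id].groupby("pre_id").size()
    from_hub = df[df["pre_id"] == hub_id].groupby("post_id").size()
    partners = sorted((set(to_hub.index) | set(from_hub.index)) - {hub_id})
    out = pd.DataFrame({
        "neuron_id": partners,
        "w_to_apl": [int(to_hub.get(p, 0)) for p in partners],
        "w_from_apl": [int(from_hub.get(p, 0)) for p in partners],
    })
    out["interacting"] = (out["w_to_apl"] > 0) & (out["w_from_apl"] > 0)
    if metadata is not None:
        meta = metadata.set_index("neuron_id")
        out["cell_class"] = [
            meta["cell_class"].get(p, "other") for p in partners
        ]
        out["kc_subtype"] = [
            meta["kc_subtype"].get(p, "unknown") for p in partners
        ]
        unknown = [p for p in partners if p not in meta.index]
        if unknown:
            log.warning("reciprocal_weights: %d partners missing from metadata "
                        "(classed 'other')", len(unknown))
    else:
        out["cell_class"] = "other"
        out["kc_subtype"] = "unknown"
    return out


@dataclass
class CorrelationResult:
    r2: float
    slope: float
    intercept: float
    n: int

    def to_dict(self) -> dict:
        return {"r2": self.r2, "slope": self.slope,
                "intercept": self.intercept, "n": self.n}


def weight_correlation(
    weights: pd.DataFrame,
    cell_class: str | None = None,
    interacting_only: bool = True,
) -> CorrelationResult:
    """OLS of ``w_from_apl`` on ``w_to_apl``; r2 is the squared Pearson
    correlation (identical to the OLS R2 for a simple linear fit).

    By default only neurons with synapses in both directions enter the
    correlation; pass ``interacting_only=False`` to use all partners.
    """
    df = weights
    if cell_class is not None:
        df = df[df["cell_class"] == cell_class]
    if interacting_only:
        df = df[df["interacting"]]
    if len(df) < 3:
        raise ValueError("weight correlation requires n >= 3 neurons")
    x = df["w_to_apl"].to_numpy(float)
    y = df["w_from_apl"].to_numpy(float)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in the predictor weights")
    res = sps.linregress(x, y)
    return CorrelationResult(r2=float(res.rvalue ** 2), slope=float(res.slope),
                             intercept=float(res.intercept), n=len(df))


@dataclass
class FractionSummary:
    per_neuron: pd.DataFrame     # neuron_id, n_tagged, n_total, fraction
    mean: float
    sem: float
    excluded: int                # neurons with only 'unknown' tags

    @property
    def n(self) -> int:
        return len(self.per_neuron)


def compartment_fractions(
    table: SynapseTable,
    hub_id: int,
    tag: str,
    metadata: pd.DataFrame | None = None,
    cell_class: str | None = None,
) -> FractionSummary:
    """Per-neuron fraction of hub->neuron synapses on a given compartment.

    Rows with tag ``"unknown"`` do not count towards the denominator;
    neurons left with an empty denominator are excluded (counted).  The
    group mean and SEM are across neurons.
    """
    df = table.df[table.df["pre_id"] == hub_id]
    if metadata is not None and cell_class is not None:
        wanted = set(metadata.loc[metadata["cell_class"] == cell_class,
                                  "neuron_id"])
        df = df[df["post_id"].isin(wanted)]
    known = df[df["compartment_tag"] != "unknown"]
    totals = known.groupby("post_id").size()
    tagged = known[known["compartment_tag"] == tag].groupby("post_id").size()
    all_neurons = df["post_id"].unique()
    excluded = int(len(all_neurons) - len(totals))
    if excluded:
        log.warning("compartment_fractions: excluded %d neurons with only "
                    "'unknown' tags", excluded)
    per_neuron = pd.DataFrame({
        "neuron_id": totals.index,
        "n_tagged": [int(tagged.get(i, 0)) for i in totals.index],
        "n_total": totals.to_numpy(int),
    })
    per_neuron["fraction"] = per_neuron["n_tagged"] / per_neuron["n_total"]
    frac = per_neuron["fraction"].to_numpy()
    mean = float(frac.mean()) if len(frac) else float("nan")
    sem = float(sps.sem(frac)) if len(frac) > 1 else float("nan")
    return FractionSummary(per_neuron=per_neuron, mean=mean, sem=sem,
                           excluded=excluded)


def subtype_localization_compare(
    fractions: pd.DataFrame,
    weights: pd.DataFrame,
    n_per_group: int = 70,
    rng_seed: int = 0,
) -> tuple[float, float, pd.DataFrame]:
    """One-way ANOVA of claw-localization fractions across KC subtypes.

    ``fractions`` is a per-neuron frame (``neuron_id, fraction``);
    ``weights`` supplies each neuron's ``kc_subtype``.  Each subtype is
    randomly subsampled to ``n_per_group`` neurons (without replacement,
    seeded; smaller groups are used whole with a warning).  Returns
    ``(F, p, tukey_contrasts)``.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    merged = fractions.merge(
        weights[["neuron_id", "kc_subtype"]], on="neuron_id", how="left")
    merged = merged[merged["kc_subtype"].notna()
                    & (merged["kc_subtype"] != "unknown")]
    groups = [g for g, _ in merged.groupby("kc_subtype")]
    if len(groups) < 2:
        raise ValueError("need at least two KC subtypes to compare")
    rng = np.random.default_rng(rng_seed)
    samples, labels = [], []
    for g, sub in merged.groupby("kc_subtype"):
        vals = sub["fraction"].to_numpy()
        if len(vals) < 3:
            raise ValueError(f"subtype {g!r} has fewer than 3 neurons")
        if len(vals) > n_per_group:
            vals = rng.choice(vals, size=n_per_group, replace=False)
        else:
            log.warning("subtype_localization_compare: %r has only %d neurons "
                        "(< %d requested)", g, len(vals), n_per_group)
        samples.append(vals)
        labels.extend([g] * len(vals))
    f_stat, p = sps.f_oneway(*samples)
    tukey = pairwise_tukeyhsd(np.concatenate(samples), np.asarray(labels))
    rows = [
        {"group_1": str(g1), "group_2": str(g2), "mean_diff": float(md),
         "p_adj": float(pa), "reject": bool(rj)}
        for g1, g2, md, pa, lo, hi, rj in tukey.summary().data[1:]
    ]
    return float(f_stat), float(p), pd.DataFrame(rows)
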