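"""Site-level bipartite visitation networks and the pooled regional metaweb.

Quantitative interaction matrices have bee species as rows and plant species
as columns, with cells holding summed interaction events.  Pooling all site
matrices gives the regional metaweb, whose positive cells define each bee
species' realized partner-plant set — the basis for scoring resource
availability at patch and landscape scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


class NetworkError(ValueError):
    pass


def build_site_network(records: pd.DataFrame, site: str) -> pd.DataFrame:
    """Bee x plant count matrix for one site (lexicographic species order)."""
    sub = records[records["site"] == site]
    if len(sub) == 0:
        raise NetworkError(f"no interaction records for site {site!r}")
    mat = (
        sub.pivot_table(
            index="bee_species", columns="plant_species", values="count",
            aggfunc="sum", fill_value=0,
        )
        .sort_index(axis=0)
        .sort_index(axis=1)
        .astype(int)
    )
    return mat


def build_all_site_networks(records: pd.DataFrame) -> dict[str, pd.DataFrame]:
    if len(records) == 0:
        raise NetworkError("no interactions")
    return {s: build_site_network(records, s) for s in sorted(records["site"].unique())}


def pool_metaweb(networks) -> tuple[pd.DataFrame, dict]:
    """Pool site matrices cell-wise into the regional metaweb.

    Accepts a dict or sequence of site matrices.  Species labels are aligned
    on the union, missing cells counting as zero.  Returns the metaweb and a
    summary with total events, unique links, and species counts.
    """
    mats = list(networks.values()) if isinstance(networks, dict) else list(networks)
    if not mats:
        raise NetworkError("no site networks to pool")
    bees = sorted(set().union(*(m.index for m in mats)))
    plants = sorted(set().union(*(m.columns for m in mats)))
    web = pd.DataFrame(0, index=bees, columns=plants, dtype=int)
    for m in mats:
        web = web.add(m.reindex(index=bees, columns=plants, fill_value=0), fill_value=0)
    web = web.astype(int)
    summary = {
        "total_events": int(web.to_numpy().sum()),
        "n_links": int((web.to_numpy() > 0).sum()),
        "n_bee_species": len(bees),
        "n_plant_species": len(plants),
    }
    return web, summary


def partner_set(bee: str, metaweb: pd.DataFrame) -> list[str]:
    """Plants the bee was observed visiting anywhere (lexicographic order).

    An empty list means the bee row exists but has no positive cells (it can
    arise after label alignment); callers must treat it as 'no known
    partners', not as an error.
    """
    if bee not in metaweb.index:
        raise NetworkError(f"bee species {bee!r} not in metaweb")
    row = metaweb.loc[bee]
    return sorted(row.index[row > 0])


def network_summaries(networks: dict[str, pd.DataFrame]) -> tuple[pd.DataFrame, dict]:
    """Per-site bee/plant richness with across-site means and s.e."""
    if not networks:
        raise NetworkError("no site networks")
    rows = [
        {"site": site, "n_bee_species": m.shape[0], "n_plant_species": m.shape[1],
         "total_events": int(m.to_numpy().sum())}
        for site, m in sorted(networks.items())
    ]
    table = pd.DataFrame(rows)

    def _mean_se(x):
        x = np.asarray(x, float)
        se = float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else float("nan")
        return float(x.mean()), se

    bee_mean, bee_se = _mean_se(table["n_bee_species"])
    plant_mean, plant_se = _mean_se(table["n_plant_species"])
    stats = {
        "bee_richness_mean": bee_mean,
        "bee_richness_se": bee_se,
        "plant_richness_mean": plant_mean,
        "plant_richness_se": plant_se,
    }
    return table, stats
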