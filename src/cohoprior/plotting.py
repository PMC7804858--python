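"""Optional figures: priority choropleths and mortality-curve plots.

Geometry (GeoJSON, WGS84) is pass-through for rendering only; no computation
depends on it.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.collections import PatchCollection
from matplotlib.patches import Polygon as MplPolygon
from shapely.geometry import shape


def priority_choropleth(priority_table: pd.DataFrame, geojson: dict,
                        out_path: str | Path, category: str | None = None) -> None:
    """Render ranks as a choropleth over subbasin polygons (smoke-level)."""
    pt = priority_table
    if category is not None:
        pt = pt[pt["category"] == category]
    ranks = pt.set_index("subbasin_id")["rank"]
    patches, values = [], []
    for feat in geojson["features"]:
        sid = feat["properties"].get("subbasin_id")
        if sid not in ranks.index:
            continue
        geom = shape(feat["geometry"])
        polys = geom.geoms if geom.geom_type == "MultiPolygon" else [geom]
        for poly in polys:
            patches.append(MplPolygon(np.asarray(poly.exterior.coords)))
            values.append(float(ranks.loc[sid]))
    fig, ax = plt.subplots(figsize=(6, 6))
    if patches:
        coll = PatchCollection(patches, cmap="viridis_r", edgecolor="0.6",
                               linewidth=0.2)
        coll.set_array(np.asarray(values))
        ax.add_collection(coll)
        fig.colorbar(coll, ax=ax, label="priority rank (1 = top)")
        ax.autoscale_view()
    ax.set_aspect("equal")
    ax.set_xlabel("longitude")
    ax.set_ylabel("latitude")
    fig.savefig(out_path, dpi=100)
    plt.close(fig)


def mortality_curve_plot(curve: pd.DataFrame, out_path: str | Path,
                         m_crit: float | None = None) -> None:
    """Posterior median mortality curve with its credible band."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.fill_between(curve["z"], curve["lower"], curve["upper"], alpha=0.3,
                    label="90% credible interval")
    ax.plot(curve["z"], curve["median"], color="k", label="posterior median")
    if m_crit is not None:
        ax.axhline(m_crit, color="r", ls="--", label=f"M_crit = {m_crit}")
    ax.set_xlabel("urbanization Z")
    ax.set_ylabel("pre-spawn mortality M")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(out_path, dpi=100)
    plt.close(fig)
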