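"""Interactive chemical-space maps as self-contained HTML documents.

Each (descriptor, method) pair becomes one scatter of the 2-D embedding,
colored by a continuous activity aggregate (mpIC50 by default, orange = low
to blue = high), sized by normalized activity SD, with a hover card showing
the compound id, canonical SMILES, the six drug-likeness properties, the
color/size source values and an embedded 2-D structure depiction. The HTML
embeds everything inline (SVG points, base64 structure images, a small
tooltip script) so the files work offline with no network fetches, and
contains no timestamps so rendering is a pure function of its inputs.
"""

from __future__ import annotations

import base64
import html
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from matplotlib import colormaps
from matplotlib.colors import LinearSegmentedColormap, to_hex
from rdkit import Chem
from rdkit.Chem.Draw import rdMolDraw2D

from chemmultiverse.activity import ActivitySummary  # noqa: F401  (type for docs)
from chemmultiverse.curation import MoleculeRecord
from chemmultiverse.descriptors import DRUGLIKENESS_COLUMNS, compute_druglikeness
from chemmultiverse.embedding import Embedding
from chemmultiverse.quality import QualityReport

#: Default continuous scale: orange (low) to blue (high).
DEFAULT_PALETTE = ("#e66101", "#fdb863", "#b2abd2", "#5e3c99", "#2c7bb6")
UNDEFINED_COLOR = "#9e9e9e"
DEPICTION_SIZE = (250, 200)


@dataclass
class PlotSpec:
    color_by: str = "mpic50"
    size_by: str = "sd_norm"
    palette: str | list[str] | tuple[str, ...] = DEFAULT_PALETTE
    min_size: float = 0.1
    title: str = "Chemical space"

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_size < 1.0:
            raise ValueError("min_size must be in [0, 1)")


def _colormap(palette) -> LinearSegmentedColormap:
    if isinstance(palette, str):
        if palette not in colormaps:
            raise ValueError(f"unknown palette {palette!r}")
        return colormaps[palette]
    return LinearSegmentedColormap.from_list("custom", list(palette))


def _depict(smiles: str) -> str:
    """Base64 SVG data URI of the 2-D structure."""
    mol = Chem.MolFromSmiles(smiles)
    drawer = rdMolDraw2D.MolDraw2DSVG(*DEPICTION_SIZE)
    drawer.DrawMolecule(mol)
    drawer.FinishDrawing()
    svg = drawer.GetDrawingText()
    return "data:image/svg+xml;base64," + base64.b64encode(svg.encode()).decode()


def _point_colors(values: np.ndarray, palette) -> list[str]:
    """Monotone map of finite values onto the colormap; NaN -> gray."""
    cmap = _colormap(palette)
    finite = np.isfinite(values)
    colors = [UNDEFINED_COLOR] * len(values)
    if finite.any():
        lo, hi = values[finite].min(), values[finite].max()
        span = hi - lo if hi > lo else 1.0
        for i in np.flatnonzero(finite):
            colors[i] = to_hex(cmap((values[i] - lo) / span))
    return colors


_PAGE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>{title}</title>
<style>
body {{ font-family: sans-serif; margin: 1em; }}
#tip {{ position: absolute; display: none; background: #fff; border: 1px solid #888;
       padding: 6px; font-size: 12px; pointer-events: none; box-shadow: 2px 2px 4px #0003; }}
circle {{ stroke: #333; stroke-width: 0.4; }}
</style></head>
<body>
<h2>{title}</h2>
<p>{subtitle}</p>
<svg id="plot" width="800" height="600" viewBox="0 0 800 600">{circles}</svg>
<div id="tip"></div>
<script>
const points = {points_json};
const tip = document.getElementById("tip");
document.querySelectorAll("#plot circle").forEach((c, i) => {{
  c.addEventListener("mousemove", (e) => {{
    const p = points[i];
    tip.innerHTML = "<b>" + p.id + "</b><br>" + p.smiles + "<br>" +
      p.props.map(q => q[0] + ": " + q[1]).join("<br>") +
      "<br><img src='" + p.img + "' width='250' height='200'>";
    tip.style.left = (e.pageX + 12) + "px";
    tip.style.top = (e.pageY + 12) + "px";
    tip.style.display = "block";
  }});
  c.addEventListener("mouseleave", () => {{ tip.style.display = "none"; }});
}});
</script>
</body></html>
"""


def render_space(
    embedding: Embedding,
    records: list[MoleculeRecord],
    summary,
    spec: PlotSpec | None = None,
    descriptor_name: str = "",
) -> str:
    """Render one embedding as a self-contained interactive HTML document.

    ``records`` are the surviving curated compounds and ``summary`` the
    activity summary DataFrame, both row-aligned with ``embedding.coords``.
    Returns the HTML text; callers decide where to write it.
    """
    spec = spec or PlotSpec()
    ok_records = [r for r in records if r.status == "ok"]
    n = embedding.n
    if len(ok_records) != n or len(summary) != n:
        raise ValueError("embedding, records and summary are not row-aligned")
    for col in (spec.color_by, spec.size_by):
        if col not in summary.columns:
            raise ValueError(f"column {col!r} not in the activity summary")

    color_vals = summary[spec.color_by].to_numpy(dtype=float)
    size_vals = summary[spec.size_by].to_numpy(dtype=float)
    size_vals = np.where(np.isfinite(size_vals), size_vals, spec.min_size)
    colors = _point_colors(color_vals, spec.palette)

    xy = embedding.coords
    lo, hi = xy.min(axis=0), xy.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    px = 40 + 720 * (xy[:, 0] - lo[0]) / span[0]
    py = 560 - 520 * (xy[:, 1] - lo[1]) / span[1]

    circles, points = [], []
    for i, rec in enumerate(ok_records):
        radius = 3.0 + 9.0 * float(np.clip(size_vals[i], 0.0, 1.0))
        circles.append(
            f'<circle cx="{px[i]:.2f}" cy="{py[i]:.2f}" r="{radius:.2f}" '
            f'fill="{colors[i]}" fill-opacity="0.85"/>'
        )
        dl = compute_druglikeness(rec.canonical_smiles)
        props = [[name, round(float(v), 3)] for name, v in zip(DRUGLIKENESS_COLUMNS, dl)]
        props.append([spec.color_by, None if not np.isfinite(color_vals[i])
                      else round(float(color_vals[i]), 3)])
        props.append([spec.size_by, round(float(size_vals[i]), 3)])
        points.append(
            {
                "id": rec.id,
                "smiles": rec.canonical_smiles,
                "props": props,
                "img": _depict(rec.canonical_smiles),
            }
        )

    subtitle = f"{descriptor_name} / {embedding.method}" if descriptor_name else embedding.method
    if embedding.explained_variance is not None:
        ev = embedding.explained_variance
        subtitle += f" — explained variance PC1 {ev[0]:.1%}, PC2 {ev[1]:.1%}"
    return _PAGE.format(
        title=html.escape(spec.title),
        subtitle=html.escape(subtitle),
        circles="\n".join(circles),
        points_json=json.dumps(points),
    )


_INDEX = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>Chemical multiverse</title>
<style>body {{ font-family: sans-serif; margin: 1em; }}
table {{ border-collapse: collapse; }} td, th {{ border: 1px solid #999; padding: 4px 10px; }}
</style></head>
<body><h2>Chemical multiverse</h2>
<table><tr><th>Space</th><th>Trustworthiness</th><th>Continuity</th>
<th>Correlation</th><th>k</th></tr>
{rows}
</table></body></html>
"""


def render_multiverse(
    results: list[tuple[str, Embedding, QualityReport]],
    records: list[MoleculeRecord],
    summary,
    out_dir: str | Path,
    spec: PlotSpec | None = None,
) -> list[Path]:
    """Write one HTML file per (descriptor, method) space plus an index page.

    The index lists every space with its quality metrics. Returns the paths
    written, index first.
    """
    if not results:
        raise ValueError("no embeddings to render")
    spec = spec or PlotSpec()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    paths, rows = [], []
    for name, emb, report in results:
        fname = f"space_{name}_{emb.method}.html"
        page_spec = PlotSpec(color_by=spec.color_by, size_by=spec.size_by,
                             palette=spec.palette, min_size=spec.min_size,
                             title=f"{spec.title}: {name} / {emb.method}")
        (out_dir / fname).write_text(
            render_space(emb, records, summary, page_spec, descriptor_name=name),
            encoding="utf-8",
        )
        paths.append(out_dir / fname)
        rows.append(
            f'<tr><td><a href="{fname}">{html.escape(name)} / {emb.method}</a></td>'
            f"<td>{report.trustworthiness:.3f}</td><td>{report.continuity:.3f}</td>"
            f"<td>{report.correlation:.3f}</td><td>{report.k}</td></tr>"
        )
    index = out_dir / "index.html"
    index.write_text(_INDEX.format(rows="\n".join(rows)), encoding="utf-8")
    return [index, *paths]
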