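"""Score landscape over size, location and shape (0-40 mm grid).

Writes the long-format grid as CSV and renders a heatmap image; each
location x shape band increases with size, irregular shape adds a constant
0.5387, and at fixed size/shape the regions order AcomA/AA > PcomA >
posterior > MCA > ICA.
"""

from pathlib import Path

from mia_score import heatmap_grid
from mia_score.score import plot_heatmap

out = Path("scratch")
out.mkdir(exist_ok=True)

grid = heatmap_grid(size_min=0, size_max=40, step=1.0)
grid.to_csv(out / "score_grid.csv", index=False)
plot_heatmap(grid, out / "score_heatmap.png")

top = grid.sort_values("score").tail(3)
print(top.to_string(index=False))
print(f"\nwrote {out/'score_grid.csv'} and {out/'score_heatmap.png'}")
# The riskiest cell of the grid is the largest irregular AcomA/AA aneurysm.
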