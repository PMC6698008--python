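"""Quantify microvessel density on the synthetic slide panel.

Runs the positive-pixel morphometry (brown-pixel rule, 8-connected
clustering, 100-px minimum component size) on every slide written by
``01_simulate_slides.py`` and compares the estimate against the
generator's pixel-exact truth.  Writes ``results/mvd_estimates.csv``.
"""

from pathlib import Path

import pandas as pd

from mvdquant import quantify_image
from mvdquant.io import load_truth, read_image, read_mask_png

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    rows = []
    for slide_dir in sorted((OUT / "slides").glob("slide_*")):
        image = read_image(slide_dir / "image.tif")
        tissue = read_mask_png(slide_dir / "tissue_mask.png")
        excluded = read_mask_png(slide_dir / "excluded_mask.png")
        truth = load_truth(slide_dir)
        result = quantify_image(image, tissue & ~excluded)
        rows.append(
            {
                "slide": slide_dir.name,
                "mvd_percent": result.mvd_percent,
                "true_percent": 100 * truth.positive_fraction,
                "error_pp": result.mvd_percent - 100 * truth.positive_fraction,
                "n_components": result.n_components,
                "analysed_pixels": result.analysed_pixels,
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "mvd_estimates.csv", index=False)
    print(table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    print(f"\nmax |error| = {table.error_pp.abs().max():.4f} pp "
          f"(recovery budget: 0.5 pp)")


if __name__ == "__main__":
    main()
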