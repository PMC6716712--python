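"""Residual diagnostics for the adjusted model.

Computes normalized quantile residuals (standard normal iff the model is
correct) and worm-plot coordinates with 95% pointwise acceptance bands;
writes a 200-point worm to results/worm_plot.csv.
"""

from common import RESULTS, fit_final, load_derived
from esrref import quantile_residuals, worm_plot_data


def main():
    derived = load_derived()
    fitted = fit_final(derived)
    RESULTS.mkdir(exist_ok=True)

    z = quantile_residuals(fitted)
    worm = worm_plot_data(z, n_points=200)
    worm.round(5).to_csv(RESULTS / "worm_plot.csv", index=False)

    inside = ((worm["deviation"] >= worm["lower"]) &
              (worm["deviation"] <= worm["upper"])).mean()
    print(f"quantile residuals: mean {z.mean():+.4f}, variance {z.var():.4f} "
          f"(standard normal under a correct model)")
    print(f"worm plot: {100 * inside:.1f}% of points inside the 95% band")


if __name__ == "__main__":
    main()
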