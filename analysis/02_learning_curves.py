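#!/usr/bin/env python
"""Aggregate times, CUSUM and inflection points per seniority group.

Reads results/simulated_log.csv (run 01 first), writes one
learning_curve_<group>.csv per group (serial_index, aggregated_time,
cusum, fitted_cusum) and, if matplotlib is available, the aggregated
time and CUSUM plots under results/figures/.
"""

from pathlib import Path

from erbt_lc import analyze_group, read_procedure_log
from erbt_lc.learning_curve import learning_curve_frame

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    log = read_procedure_log(RESULTS / "simulated_log.csv")
    results = {}
    for group in ("junior", "senior"):
        res = analyze_group(log, group, method="raw_argmax")
        results[group] = res
        frame = learning_curve_frame(res)
        frame.to_csv(RESULTS / f"learning_curve_{group}.csv", index=False,
                     float_format="%.6f")
        infl = res["inflection"].index
        fit = res["fit"]
        print(f"{group}: inflection at procedure {infl} "
              f"(CUSUM argmax; poly fit degree {fit.degree}, "
              f"adj R² {fit.r2_adjusted:.3f})")

    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:
        print("matplotlib not available; skipping figures")
        return
    figdir = RESULTS / "figures"
    figdir.mkdir(exist_ok=True)
    for group, res in results.items():
        frame = learning_curve_frame(res)
        fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(7, 6), sharex=True)
        ax1.plot(frame["serial_index"], frame["aggregated_time"], "o-")
        ax1.set_ylabel("aggregated time (min)")
        ax1.set_title(f"{group} endoscopists")
        ax2.plot(frame["serial_index"], frame["cusum"], "o-", label="CUSUM")
        ax2.plot(frame["serial_index"], frame["fitted_cusum"], "--", label="poly fit")
        ax2.axvline(res["inflection"].index, color="k", ls=":",
                    label=f"inflection = {res['inflection'].index}")
        ax2.set_xlabel("serial procedure")
        ax2.set_ylabel("CUSUM (min)")
        ax2.legend()
        fig.tight_layout()
        fig.savefig(figdir / f"learning_curve_{group}.png", dpi=120)
        plt.close(fig)
    print(f"figures written to {figdir}")


if __name__ == "__main__":
    main()
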