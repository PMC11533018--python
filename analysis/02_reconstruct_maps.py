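"""Reconstruct QSM and R2* from simulated MGRE data and score ROI recovery.

Runs the full chain (unwrap -> field fit -> reliability -> V-SHARP -> TKD)
on a noiseless and a noisy (SNR 50) acquisition of the default phantom and
writes the per-ROI recovery table to results/map_recovery.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from ironmap.forward import forward_field, simulate_mgre
from ironmap.geometry import AcquisitionGeometry
from ironmap.phantom import DGM_STRUCTURES, make_phantom
from ironmap.qsm import ReconConfig, reconstruct_qsm
from ironmap.relaxometry import fit_r2star
from ironmap.roi import trim_and_mean


def score(truth, chi_map, relax, label):
    rows = []
    for roi in DGM_STRUCTURES:
        mask_q = truth.roi_mask(roi) & chi_map.mask
        mask_r = truth.roi_mask(roi) & relax.mask
        est_q, _ = trim_and_mean(chi_map.chi[mask_q])
        tru_q, _ = trim_and_mean(truth.chi[mask_q])
        est_r, _ = trim_and_mean(relax.r2star[mask_r])
        tru_r, _ = trim_and_mean(truth.r2star[mask_r])
        rows.append({
            "condition": label, "roi_name": roi,
            "qsm_true_ppb": tru_q, "qsm_est_ppb": est_q,
            "qsm_rel_err": abs(est_q - tru_q) / abs(tru_q),
            "r2star_true_s": tru_r, "r2star_est_s": est_r,
            "r2star_rel_err": abs(est_r - tru_r) / tru_r,
        })
    return rows


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    geometry = AcquisitionGeometry()
    truth = make_phantom(geometry, seed=args.seed)
    field = forward_field(truth, geometry)
    cfg = ReconConfig(reference="none")   # absolute scale, comparable to truth

    rows = []
    for label, snr in (("noiseless", np.inf), ("snr50", 50.0)):
        series = simulate_mgre(truth, field, geometry, snr=snr, seed=args.seed)
        chi_map, _, reliable = reconstruct_qsm(series, truth.brain_mask, cfg)
        relax = fit_r2star(series, truth.brain_mask)
        relax.mask &= reliable
        rows.extend(score(truth, chi_map, relax, label))

    table = pd.DataFrame(rows)
    args.out.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out / "map_recovery.csv", index=False)
    print(table.to_string(index=False, float_format=lambda v: f"{v:8.3f}"))
    worst = table.groupby("condition")[["qsm_rel_err", "r2star_rel_err"]].max()
    print("\nworst-case ROI relative errors:")
    print(worst.to_string(float_format=lambda v: f"{v:6.3f}"))
    print(f"\nrecovery table -> {args.out / 'map_recovery.csv'}")


if __name__ == "__main__":
    main()
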