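#!/usr/bin/env python
"""Permutational multivariate analysis of the scenario snapshots.

Reads the snapshot community matrices written by 02_run_scenarios.py and,
per site and snapshot year, normalises the variables, computes Euclidean
distances and runs the three-factor PERMANOVA (water quality x fishing x
bleaching, permutation of residuals under a reduced model) plus PERMDISP
over the 18 scenario groups. For year 20 it additionally computes the
mean-distance stressor effect sizes with the antagonism/additivity/synergy
classification, the 153 pairwise scenario tests, and CAP / nMDS
ordinations with Spearman variable vectors.

Tables are written under results/multivariate/<site>/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from reefcast.mvstats import (
    axis_correlations,
    drop_constant_columns,
    cap,
    distance_matrix,
    nmds,
    normalise,
    pairwise_permanova,
    permanova,
    permdisp,
)
from reefcast.output import write_results
from reefcast.pipeline import interaction_classification
from reefcast.sites import ARCHETYPE_LABELS

GROUP_COLS = ["scenario", "fishing", "bleaching", "water_quality", "replicate"]


def analyse_site(site_dir: Path, out_dir: Path, n_perm: int, seed: int) -> None:
    rng = np.random.default_rng(seed)
    outputs = {}
    for snap in sorted(site_dir.glob("snapshot_y*.csv")):
        year = int(snap.stem.split("snapshot_y")[1])
        table = pd.read_csv(snap)
        raw, dropped = drop_constant_columns(table.drop(columns=GROUP_COLS))
        if dropped:
            print(f"  year {year:2d}: dropping constant variable(s) {dropped}")
        data = normalise(raw)
        dist = distance_matrix(data)
        dist.labels = table[GROUP_COLS]

        res = permanova(dist, table[["water_quality", "fishing", "bleaching"]],
                        n_perm=n_perm, seed=int(rng.integers(2**31 - 1)))
        outputs[f"permanova_y{year}"] = res.table.reset_index()
        sig = res.table["p_perm"].dropna() < 0.05
        print(f"  year {year:2d}: significant PERMANOVA terms: "
              f"{', '.join(sig[sig].index) or 'none'}")

        disp = permdisp(dist, table["scenario"], n_perm=n_perm,
                        seed=int(rng.integers(2**31 - 1)))
        outputs[f"permdisp_y{year}"] = (
            disp.group_means.rename("mean_dist_to_centroid")
            .rename_axis("scenario").reset_index()
        )

        if year == 20:
            effects = interaction_classification(dist, table["scenario"])
            outputs["interaction_effects_y20"] = effects
            print("  year 20 stressor interactions:")
            for _, row in effects.iterrows():
                print(f"    {row['interaction']:24s} combined="
                      f"{row['effect_combined']:.2f} vs sum="
                      f"{row['effect_a'] + row['effect_b']:.2f} -> "
                      f"{row['classification']}")
            outputs["pairwise_y20"] = pairwise_permanova(
                dist, table["scenario"], n_perm=n_perm,
                seed=int(rng.integers(2**31 - 1)))
            ord_cap = cap(dist, table["scenario"])
            ord_mds = nmds(dist, k_dims=2, n_restarts=20,
                           seed=int(rng.integers(2**31 - 1)))
            print(f"  CAP LOO allocation success {ord_cap.allocation_success:.1f}% "
                  f"(m={ord_cap.m_axes}); nMDS 2D stress = {ord_mds.stress:.2f}")
            coords = pd.DataFrame(
                ord_mds.coordinates, columns=["nmds_1", "nmds_2"])
            outputs["nmds_y20"] = pd.concat([table[GROUP_COLS], coords], axis=1)
            outputs["nmds_vectors_y20"] = axis_correlations(
                data, ord_mds.coordinates, threshold=0.20
            ).rename_axis("variable").reset_index()
    write_results(outputs, out_dir)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--snapshots", type=Path,
                        default=Path("results/scenarios"))
    parser.add_argument("--out", type=Path, default=Path("results/multivariate"))
    parser.add_argument("--nperm", type=int, default=999,
                        help="permutations per test (4999 at full study scale)")
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--sites", nargs="*", default=list(ARCHETYPE_LABELS))
    args = parser.parse_args()

    for label in args.sites:
        site_dir = args.snapshots / label
        if not site_dir.exists():
            raise SystemExit(
                f"{site_dir} not found - run analysis/02_run_scenarios.py first"
            )
        print(f"{label}:")
        analyse_site(site_dir, args.out / label, args.nperm, args.seed)
    print(f"\nstatistics written under {args.out}/")


if __name__ == "__main__":
    main()
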