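"""Two-cohort planted-contrast study: does the pipeline see a 1.5x flow region?

Builds two synthetic cohorts (n=5 each) identical except for a 1.5x
velocity multiplier in a box subregion of cohort B, runs every subject
through preprocess -> rOMT -> pathlines -> speed map, and compares the
cohorts with voxel-wise pooled-variance t maps.  Reports the regional
mean-speed ratio (target 1.5) and the fraction of subregion voxels
significant in the B > A direction.
"""

from pathlib import Path

from glymphflow.pipeline import StudyConfig, run_group_study
from glymphflow.synthetic import BolusSpec, PhantomSpec, RegionScale

OUT = Path(__file__).resolve().parents[1] / "results" / "group_study"
SEED = 20251001

REGION = ((8, 5, 5), (12, 11, 11))


def build_config(seed: int = SEED, out_dir: str | None = str(OUT)) -> StudyConfig:
    base = dict(
        grid_dims=(16, 16, 16),
        n_frames=3,
        velocity_kind="constant",
        velocity_magnitude=0.3,
        sigma_true=0.0,
        noise_sd=1.0,
        bolus=BolusSpec(center_mm=(1.65, 2.25, 2.25), width_mm=0.9, amplitude=30.0),
    )
    return StudyConfig(
        phantom_a=PhantomSpec(**base),
        phantom_b=PhantomSpec(
            region_scale=RegionScale(lo_vox=REGION[0], hi_vox=REGION[1], factor=1.5),
            **base,
        ),
        n_a=5,
        n_b=5,
        region=REGION,
        seed=seed,
        out_dir=out_dir,
    )


def main() -> None:
    report = run_group_study(build_config())
    print(
        f"regional mean-speed ratio B/A: {report.regional_ratio_b_over_a:.3f} "
        "(planted 1.5)"
    )
    print(
        f"fraction of subregion voxels significant for B > A: "
        f"{report.region_sig_fraction:.3f}"
    )
    print(f"per-subject metrics and maps written under {OUT}")


if __name__ == "__main__":
    main()
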