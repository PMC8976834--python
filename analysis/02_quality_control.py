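"""Variant- and sample-level QC of the simulated study.

Reports how many variants each filter removed (GQ masking is applied
before the missingness computation) and which samples were excluded.
"""

import pandas as pd

from _common import get_pipeline, seed_from_argv, write


def main() -> None:
    seed = seed_from_argv()
    print(f"[02] quality control (seed {seed})")
    r = get_pipeline(seed)
    rep = r.variant_report

    reasons = (
        rep.loc[~rep["keep"], "fail_reasons"].str.split(",").explode()
        .value_counts().rename("n_variants")
    )
    print(f"  variants: {int(rep['keep'].sum())} kept / {len(rep)} total")
    print(reasons.to_string())
    write(reasons.to_frame(), "02_variant_filter_reasons.tsv")

    kept_common = int((rep["keep"] & rep["common"]).sum())
    kept_rare = int((rep["keep"] & ~rep["common"]).sum())
    print(f"  kept common (MAF > 1%): {kept_common}; kept rare: {kept_rare}")

    sample_reasons = r.sample_report["reason"].value_counts().rename("n_samples")
    print(f"  samples: {len(r.kept_samples)} kept, "
          f"{len(r.sample_report)} removed")
    print(sample_reasons.to_string())
    write(sample_reasons.to_frame(), "02_sample_filter_reasons.tsv")

    summary = pd.DataFrame(
        {
            "statistic": ["variants_kept", "variants_total",
                          "samples_kept", "samples_total"],
            "value": [int(rep["keep"].sum()), len(rep),
                      len(r.kept_samples),
                      len(r.kept_samples) + len(r.sample_report)],
        }
    )
    write(summary, "02_qc_summary.tsv", index=False)


if __name__ == "__main__":
    main()
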