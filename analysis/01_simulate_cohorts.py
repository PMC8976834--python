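"""Simulate the synthetic study: one case cohort, two disease-control
cohorts, common and rare variants with planted effects.

Writes a cohort summary and a small demonstration VCF slice.
"""

import pandas as pd

from _common import RESULTS, get_pipeline, seed_from_argv, write


def main() -> None:
    seed = seed_from_argv()
    print(f"[01] simulating the default study (seed {seed})")
    r = get_pipeline(seed)
    cfg = r.config
    truth = r.truth

    summary = pd.DataFrame(
        {
            "n_samples": truth.samples["cohort"].value_counts(),
        }
    )
    print(summary)
    write(summary, "01_cohort_summary.tsv")

    effects = pd.DataFrame(
        [(e.target, e.phenotype, e.odds_ratio) for e in cfg.effect_table],
        columns=["target", "phenotype", "odds_ratio"],
    )
    print(f"  {cfg.m_common} common + {cfg.m_rare} rare variants "
          f"in {cfg.n_genes} genes; {len(effects)} planted effects")
    write(effects, "01_planted_effects.tsv", index=False)

    # a small text VCF slice for format interoperability demos
    from dcgwas.simulate import simulate_cohorts, simulate_read_evidence
    from dcgwas.vcfio import write_vcf
    import dataclasses

    demo_cfg = dataclasses.replace(
        cfg, n_case=30, n_ctrl_a=10, n_ctrl_b=10, m_common=10,
        m_rare_per_gene=2, n_genes=5, batch_size=2000, effect_table=[],
    )
    mx, _, _, _ = simulate_cohorts(demo_cfg)
    mx.ad_ref, mx.ad_alt, mx.gq = simulate_read_evidence(
        mx, mean_depth=cfg.mean_depth, seed=seed + 1
    )
    RESULTS.mkdir(exist_ok=True)
    write_vcf(mx, str(RESULTS / "01_demo_genotypes.vcf"))
    print("  wrote results/01_demo_genotypes.vcf")


if __name__ == "__main__":
    main()
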