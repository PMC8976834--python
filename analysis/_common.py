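"""Shared plumbing for the numbered analysis drivers.

The synthetic study is fully determined by one seed; the pipeline
result is cached under scratch/ so the numbered scripts can be run
independently without recomputing the whole study each time.
"""

from __future__ import annotations

import pathlib
import pickle
import sys

ROOT = pathlib.Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

DEFAULT_SEED = 7


def get_pipeline(seed: int = DEFAULT_SEED, n_perm: int = 5000):
    """Run (or load the cached) default synthetic study for a seed."""
    from dcgwas.pipeline import default_study_config, run_pipeline

    SCRATCH.mkdir(exist_ok=True)
    cache = SCRATCH / f"pipeline_seed{seed}.pkl"
    if cache.exists():
        with open(cache, "rb") as fh:
            return pickle.load(fh)
    res = run_pipeline(default_study_config(seed=seed), n_perm=n_perm)
    with open(cache, "wb") as fh:
        pickle.dump(res, fh)
    return res


def write(df, name: str, index: bool = True) -> pathlib.Path:
    RESULTS.mkdir(exist_ok=True)
    path = RESULTS / name
    df.to_csv(path, sep="\t", index=index)
    print(f"  wrote {path.relative_to(ROOT)}")
    return path


def seed_from_argv() -> int:
    return int(sys.argv[1]) if len(sys.argv) > 1 else DEFAULT_SEED
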