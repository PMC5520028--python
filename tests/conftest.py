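import json

import pytest

from genopotential.core_model import Thresholds
from genopotential.pipeline import RunConfig, make_demo, run_pipeline


@pytest.fixture(scope="session")
def thresholds():
    return Thresholds()


@pytest.fixture(scope="session")
def demo(tmp_path_factory):
    """One demo community (seed 1), generated and run once per session.

    Yields a dict with the bundle paths, the truth-derived expected summary,
    and the summary the pipeline actually produced.
    """
    outdir = tmp_path_factory.mktemp("demo")
    paths = make_demo(1, str(outdir))
    config = RunConfig.from_json(paths["config"])
    summary = run_pipeline(config)
    with open(paths["expected_summary"]) as fh:
        expected = json.load(fh)
    return {
        "paths": paths,
        "outdir": str(outdir),
        "config": config,
        "summary": summary,
        "expected": expected,
    }
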