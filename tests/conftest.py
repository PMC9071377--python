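"""Shared fixtures: the packaged profile, a default simulated bundle and
a full pipeline report, built once per session."""

import pytest

from bhlhkit import (
    AnalysisConfig,
    default_config,
    default_profile,
    emit_files,
    load_bundle_dir,
    run_full_analysis,
    simulate_pangenome,
)


@pytest.fixture(scope="session")
def profile():
    return default_profile()


@pytest.fixture(scope="session")
def default_bundle():
    return simulate_pangenome(default_config(seed=42))


@pytest.fixture(scope="session")
def bundle_dir(default_bundle, tmp_path_factory):
    path = tmp_path_factory.mktemp("bundle")
    emit_files(default_bundle, path)
    return path


@pytest.fixture(scope="session")
def report(bundle_dir):
    config = AnalysisConfig(**load_bundle_dir(bundle_dir), seed=42)
    return run_full_analysis(config)
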