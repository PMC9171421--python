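import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from orfdom import Transcript, profile_transcript, scan_frames, synthesize_fixture


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240611)


@pytest.fixture(scope="session")
def fixture_set():
    """Seeded coding-like / noncoding-like transcript set (500 + 500)."""
    return synthesize_fixture(500, 500, (200, 2000), seed=13)


@pytest.fixture(scope="session")
def fixture_profiles(fixture_set):
    return [profile_transcript(scan_frames(t), t.label) for t in fixture_set]


@pytest.fixture
def two_record_fasta(tmp_path):
    path = tmp_path / "two.fa"
    path.write_text(">NM_000001 some coding gene\nATGAAATGA\n>NR_000002\nauguaa\n")
    return path
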