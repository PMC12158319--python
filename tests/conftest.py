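import pytest

from courtgaze.neon_io import DeviceSpec, read_session
from courtgaze.synth import SceneScript, generate_session

# A small scene keeps rendering fast while preserving the 30/200 Hz rate
# structure and the white-vs-navy jersey geometry.
SMALL_DEVICE = DeviceSpec(scene_width=480, scene_height=360)


@pytest.fixture(scope="session")
def ideal_recording(tmp_path_factory):
    """A 90-frame noise-free synthetic recording plus its ground truth."""
    out = tmp_path_factory.mktemp("rec_ideal")
    script = SceneScript(seed=7, n_frames=90, device=SMALL_DEVICE)
    path, gt = generate_session(script, out)
    return path, gt, script


@pytest.fixture(scope="session")
def ideal_session(ideal_recording):
    path, gt, script = ideal_recording
    return read_session(path, device=script.device), gt, script
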