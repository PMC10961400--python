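import numpy as np
import pytest

from ppgstiff import config as cfg
from ppgstiff.experiments import beat_from_template
from ppgstiff.synth_pulse import BeatTemplate, SubjectSpec, make_beat_template, render_record


@pytest.fixture(scope="session")
def default_cfg():
    return cfg.default_config()


@pytest.fixture(scope="session")
def gaussian_beat():
    """Single-Gaussian pulse (peak at 0.30 s, sigma 0.05 s, period 1 s)."""
    template = BeatTemplate(((1.0, 0.30, 0.05),), 1.0, "1", {"direct_peak": 0.30})
    return template, beat_from_template(template, 1000)


@pytest.fixture(scope="session")
def class1_beat():
    template = make_beat_template("1", 5.0)
    return template, beat_from_template(template, 1000)


@pytest.fixture(scope="session")
def clean_record():
    spec = SubjectSpec("clean", 44, 1.76, 7.0, "2", seed=3)
    return render_record(spec, duration=40.0, fs=1000.0)


@pytest.fixture(scope="session")
def noiseless_record():
    spec = SubjectSpec("quiet", 44, 1.76, 7.0, "2", noise_sd=0.0, seed=3)
    return render_record(spec, duration=40.0, fs=1000.0)
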