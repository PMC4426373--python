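"""Packaged per-trait model structures (the study's fitted-model layout)."""

from importlib import resources

import yaml


def load_presets(name: str = "study_models.yaml") -> dict:
    with resources.files(__package__).joinpath(name).open("r") as fh:
        return yaml.safe_load(fh)
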