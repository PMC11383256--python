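"""Bundled scenario JSON files for the synthetic pipeline."""

from importlib.resources import files


def load_text(name: str) -> str:
    """Return the JSON text of a bundled scenario (without extension)."""
    return files(__name__).joinpath(f"{name}.json").read_text()
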