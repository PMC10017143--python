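"""rxpatterns: time-varying polypharmacy pattern discovery from linked
primary-care medication and diagnosis event tables, via exploratory factor
analysis over pre-diagnosis period windows."""

__version__ = "0.1.0"

from importlib import resources as _resources


def demo_config_path() -> str:
    """Path to the bundled demonstration run configuration."""
    return str(_resources.files("rxpatterns") / "configs" / "demo.yaml")
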