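"""Access to YAML data files bundled with the package."""
from importlib import resources


def read_text(filename: str) -> str:
    return (resources.files("modpep") / "data" / filename).read_text()
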