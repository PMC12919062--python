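"""Regenerate the packaged default prior set (src/pulsedecon/data/default_priors.json).

Run from the repository root after changing the synthetic template family or
the prior-fitting procedure:

    python scripts/build_default_priors.py
"""
from pathlib import Path

from pulsedecon.templates import build_default_priors

out = Path(__file__).resolve().parents[1] / "src" / "pulsedecon" / "data" / "default_priors.json"
priors = build_default_priors()
priors.save(out)
print(f"wrote {out}")
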