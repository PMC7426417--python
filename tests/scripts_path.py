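"""Make the repository's scripts/ directory importable from the tests."""

import sys
from pathlib import Path

_scripts = Path(__file__).resolve().parent.parent / "scripts"
if str(_scripts) not in sys.path:
    sys.path.insert(0, str(_scripts))
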