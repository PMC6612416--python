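#!/usr/bin/env python
"""Download the optional reference image used by the example-image parity test.

Fetches the example fluorescence micrograph packaged with the upstream
colocalization workflow (GPL-3) into tests/data/ so that the reference
parity test runs.  Needs network access; everything else in the test suite
is self-contained.
"""

import urllib.request
from pathlib import Path

URL = "https://raw.githubusercontent.com/ropensci/colocr/master/inst/extdata/Image0003_.jpg"
DEST = Path(__file__).resolve().parent.parent / "tests" / "data" / "Image0003_.jpg"


def main() -> None:
    DEST.parent.mkdir(parents=True, exist_ok=True)
    print(f"downloading {URL} -> {DEST}")
    urllib.request.urlretrieve(URL, DEST)
    print(f"done ({DEST.stat().st_size} bytes)")


if __name__ == "__main__":
    main()
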