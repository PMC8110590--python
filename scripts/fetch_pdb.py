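#!/usr/bin/env python
"""One-time download of the deposited OCP coordinate files.

Fetches the OCP^WW structures (6T6K, 6T6M, 6T6O) and the WT reference
(4XB5) from the RCSB into data/pdb/, where the geometry acceptance test and
``ocpkin geometry`` expect them.  Requires network access; the rest of the
package runs fully offline.
"""

from __future__ import annotations

import sys
import urllib.request
from pathlib import Path

ENTRIES = ("6T6K", "6T6M", "6T6O", "4XB5")
URL = "https://files.rcsb.org/download/{}.pdb"


def main() -> int:
    dest = Path(__file__).resolve().parent.parent / "data" / "pdb"
    dest.mkdir(parents=True, exist_ok=True)
    failures = 0
    for code in ENTRIES:
        target = dest / f"{code}.pdb"
        if target.exists():
            print(f"{code}: already present")
            continue
        try:
            urllib.request.urlretrieve(URL.format(code), target)
            print(f"{code}: downloaded -> {target}")
        except OSError as exc:
            print(f"{code}: download failed ({exc})", file=sys.stderr)
            failures += 1
    return 1 if failures else 0


if __name__ == "__main__":
    raise SystemExit(main())
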