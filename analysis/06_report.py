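#!/usr/bin/env python
"""Regenerate the human-readable report from the stage outputs."""
import argparse
import json

import striatum_mvpa as sm
from common import RESULTS


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.parse_args()
    manifest = json.loads((RESULTS / "manifest.json").read_text())
    sm.write_report(manifest, RESULTS)
    print(f"report written to {RESULTS / 'report.md'}")


if __name__ == "__main__":
    main()
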