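#!/usr/bin/env python
"""Render the markdown report for results/run/ into results/report.md."""

from pathlib import Path

from prediab.report import render_report

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    text = render_report(ROOT / "run")
    out = ROOT / "report.md"
    out.write_text(text, encoding="utf-8")
    print(text.split("## Baseline characteristics")[0])
    print(f"full report written to {out}")


if __name__ == "__main__":
    main()
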