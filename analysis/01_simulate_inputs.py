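#!/usr/bin/env python
"""Generate every synthetic input the downstream analyses consume.

Runs the `simulate` pipeline stage with the study's effect structure: an F2
cross of 222 Clock-mutant heterozygotes with a semidominant suppressor locus,
a 16-strain SNP panel with a 900-kb ancestral divergent segment, a rhythmic
activity record, a saturation-binding titration, paired ChIP-seq peak sets
and allele-mixture qPCR/colony data under an 80:20 expression bias.
"""

from pathlib import Path

from socmap import pipeline

OUT = Path(__file__).resolve().parents[1] / "results" / "inputs"


def main() -> None:
    manifest = pipeline.run_pipeline(
        {"seed": 20130409, "out_dir": str(OUT), "stages": ["simulate"]}
    )
    stage = manifest.stages["simulate"]
    print(f"wrote {len(stage['outputs'])} input files to {OUT}")
    print(f"implanted QTL at marker index {stage['qtl_marker']}")
    for name in stage["outputs"]:
        print(f"  {name}")


if __name__ == "__main__":
    main()
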