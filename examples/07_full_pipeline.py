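"""The orchestrated end-to-end run from a YAML configuration.

Equivalent to `mirxplat run --config demo.yaml`: simulate both platforms and
the qPCR arm, normalize each arm vendor-style, call detection, test
differential expression per sex, summarize cross-platform concordance and GC
discordance, cluster the significant log2-ratio profiles, and write every
stage output plus a provenance log.
"""

import json
import tempfile
from pathlib import Path

import yaml

from mirxplat import RunConfig, run_pipeline

workdir = Path(tempfile.mkdtemp(prefix="mirxplat_demo_"))
config = {
    "seed": 7,
    "output_dir": str(workdir / "out"),
    "simulation": {
        "n_mirnas": 200,
        "noise_sd": 0.3,
        "planted_effects": {
            "sim-miR-0001": [2.5, None],
            "sim-miR-0002": [2.0, "M"],
            "sim-miR-0003": [2.0, "F"],
        },
    },
}
cfg_path = workdir / "demo.yaml"
cfg_path.write_text(yaml.safe_dump(config))

result = run_pipeline(RunConfig.from_yaml(cfg_path))

print(f"outputs written to {result.output_dir}:")
for p in sorted(result.output_dir.iterdir()):
    print(f"  {p.name}")
print()
print("significant miRNAs per platform arm and sex:")
for platform in ("A", "B"):
    for sex in ("M", "F"):
        names = list(result.significant[platform][sex].index)
        print(f"  platform {platform}, {sex}: {names}")
print()
print("cross-platform overlap of significant calls:")
print(json.dumps(result.de_overlap.to_dict(), indent=2, sort_keys=True))
print()
print(
    "Platform A is GC-biased by default: whether a planted effect is found by\n"
    "one platform or both depends on the GC content each miRNA was assigned.\n"
    "The concordance summary and the GC discordance block in concordance.json\n"
    "quantify that disagreement; detection_by_group holds the per-group\n"
    "cross-platform Venn counts and universe fractions."
)
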