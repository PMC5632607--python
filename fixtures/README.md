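# Fixture scenario

`scenario.json` records the seed and the full generator configuration of the
package's reference synthetic scenario (60x60 grid, 6 environmental layers,
3 virtual species).  Every generator in `admkit.synthetic` is deterministic
given its seed, so the scenario's rasters and occurrence tables are
regenerated bit-identically at test time instead of being stored:

```bash
python -c "
import json
from admkit.pipeline import StudyConfig, run_study, study_summary
spec = json.load(open('fixtures/scenario.json'))
print(study_summary(run_study(spec['seed'], StudyConfig(**spec['config']))))
"
```

The test suite asserts this reproducibility (`tests/test_pipeline_cli.py`).
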