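.PHONY: test acceptance

test:
	python -m pytest -q tests/

acceptance:
	python scripts/acceptance.py --seed 1 --out results/acceptance.json
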