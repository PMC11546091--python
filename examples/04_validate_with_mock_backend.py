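"""Instruction prompts and context validation with the mock backend.

Builds an instruction prompt for a candidate protein pair, runs it
through the deterministic mock backend, and parses the verdict.
"""

from kgppi.corpus import InstructionExample, build_instruction
from kgppi.validator import MockBackend, validate_pair

backend = MockBackend()

contexts = {
    "interaction described": "ERBB2X phosphorylates SHC1X upon receptor activation.",
    "co-mention only": "ERBB2X was overexpressed in tumours. SHC1X levels were unchanged.",
}

for label, context in contexts.items():
    example = InstructionExample(
        prompt=build_instruction(context, "ERBB2X", "SHC1X"),
        pair=("ERBB2X", "SHC1X"), label=1, doc_id="demo")
    verdict = validate_pair(example, backend)
    print(f"{label}:")
    print(f"  decision {verdict.decision} (confidence {verdict.confidence})")
    print(f"  explanation: {verdict.explanation}")

print("\nA pair counts as confirmed only when some mentioning document "
      "yields a YES verdict; co-mention without an interaction verb is rejected.")
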