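"""Dry-run a tool on synthetic inputs without touching the filesystem.

`random_invocation` draws a schema-conformant invocation by rejection
sampling; `simulate` builds the full command-line plan for it without
executing anything.  Both are deterministic for a fixed seed, which is
what makes descriptor test suites reproducible.
"""

from clidesc import generate_random_descriptor, random_invocation, simulate

descriptor = generate_random_descriptor(seed=7, n_inputs=4, n_outputs=2)
print("descriptor:", descriptor.name)
print("template:  ", descriptor.command_line)

for seed in range(3):
    invocation = random_invocation(descriptor, seed=seed)
    plan = simulate(descriptor, invocation)
    print(f"seed {seed}: {plan.command}")

# simulate with no invocation draws one itself
print("auto:  ", simulate(descriptor, seed=41).command)
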