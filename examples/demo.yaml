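# Demo run: generate a synthetic dataset with the launch simulator
# (5 animals x 3 control + 10 platform-A + 2 platform-B jumps) and push it
# through the full analysis pipeline.
#
#   springboard all -c examples/demo.yaml
output_dir: out/demo
seed: 1
frame_rate: 1000
synthetic: {}
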