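# Desk-scale configuration: small residual U-Net on 32³ patches.
# Keys mirror the NetworkConfig / LossConfig / TrainConfig / PhantomConfig
# dataclass fields one-to-one; command-line flags override these values.

phantom:
  shape: [48, 48, 48]
  radii: [11.0, 7.0, 4.0]
  radius_jitter: 1.0
  center_jitter: 2.0
  noise_sd: 0.05

network:
  variant: res_unet
  depth: 4
  base_channels: 8
  channel_cap: 64
  in_channels: 5
  deep_supervision: true

loss:
  alpha: 0.7
  secondary: focal
  gamma: 2.0

training:
  learning_rate: 1.0e-4
  weight_decay: 1.0e-5
  batch_size: 2
  patch_size: [32, 32, 32]
  max_epochs: 30
  patience: 10
  fg_bias: 0.5
  patches_per_case: 4
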