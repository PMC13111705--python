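id,study,n_human_A,n_human_S,n_ai_A,n_ai_S,pi_direction,acc_human,acc_ai,acc_pi,posterior_A
S2-001,2,3,0,0,1,S,0.56000000000000005,0.55000000000000004,0.56999999999999995,0.559951
S2-002,2,0,3,1,0,A,0.56000000000000005,0.55000000000000004,0.56999999999999995,0.440049
S2-003,2,0,1,3,0,S,0.55000000000000004,0.56000000000000005,0.56999999999999995,0.559951
S2-004,2,1,0,0,3,A,0.55000000000000004,0.56000000000000005,0.56999999999999995,0.440049
S2-005,2,3,0,0,1,S,0.57999999999999996,0.56000000000000005,0.62,0.559125
S2-006,2,0,3,1,0,A,0.57999999999999996,0.56000000000000005,0.62,0.440875
S2-007,2,0,1,3,0,S,0.56000000000000005,0.57999999999999996,0.62,0.559125
S2-008,2,1,0,0,3,A,0.56000000000000005,0.57999999999999996,0.62,0.440875
S2-009,2,3,0,0,1,S,0.56999999999999995,0.55000000000000004,0.59999999999999998,0.559570
S2-010,2,0,3,1,0,A,0.56999999999999995,0.55000000000000004,0.59999999999999998,0.440430
S2-011,2,0,1,3,0,S,0.55000000000000004,0.56999999999999995,0.59999999999999998,0.559570
S2-012,2,1,0,0,3,A,0.55000000000000004,0.56999999999999995,0.59999999999999998,0.440430
S2-013,2,3,0,0,1,S,0.55000000000000004,0.65000000000000002,0.65000000000000002,0.346136
S2-014,2,0,3,1,0,A,0.55000000000000004,0.65000000000000002,0.65000000000000002,0.653864
S2-015,2,0,1,3,0,S,0.65000000000000002,0.55000000000000004,0.65000000000000002,0.346136
S2-016,2,1,0,0,3,A,0.65000000000000002,0.55000000000000004,0.65000000000000002,0.653864
S2-017,2,3,0,0,1,S,0.55000000000000004,0.58999999999999997,0.69999999999999996,0.352230
S2-018,2,0,3,1,0,A,0.55000000000000004,0.58999999999999997,0.69999999999999996,0.647770
S2-019,2,0,1,3,0,S,0.58999999999999997,0.55000000000000004,0.69999999999999996,0.352230
S2-020,2,1,0,0,3,A,0.58999999999999997,0.55000000000000004,0.69999999999999996,0.647770
S2-021,2,3,0,0,1,S,0.55000000000000004,0.60999999999999999,0.68000000000000005,0.354556
S2-022,2,0,3,1,0,A,0.55000000000000004,0.60999999999999999,0.68000000000000005,0.645444
S2-023,2,0,1,3,0,S,0.60999999999999999,0.55000000000000004,0.68000000000000005,0.354556
S2-024,2,1,0,0,3,A,0.60999999999999999,0.55000000000000004,0.68000000000000005,0.645444
S2-025,2,3,0,0,1,S,0.55000000000000004,0.69999999999999996,0.69999999999999996,0.251132
S2-026,2,0,3,1,0,A,0.55000000000000004,0.69999999999999996,0.69999999999999996,0.748868
S2-027,2,0,1,3,0,S,0.69999999999999996,0.55000000000000004,0.69999999999999996,0.251132
S2-028,2,1,0,0,3,A,0.69999999999999996,0.55000000000000004,0.69999999999999996,0.748868
S2-029,2,3,0,0,1,S,0.55000000000000004,0.62,0.77000000000000002,0.250519
S2-030,2,0,3,1,0,A,0.55000000000000004,0.62,0.77000000000000002,0.749481
S2-031,2,0,1,3,0,S,0.62,0.55000000000000004,0.77000000000000002,0.250519
S2-032,2,1,0,0,3,A,0.62,0.55000000000000004,0.77000000000000002,0.749481
S2-033,2,3,0,0,1,S,0.55000000000000004,0.66000000000000003,0.73999999999999999,0.248384
S2-034,2,0,3,1,0,A,0.55000000000000004,0.66000000000000003,0.73999999999999999,0.751616
S2-035,2,0,1,3,0,S,0.66000000000000003,0.55000000000000004,0.73999999999999999,0.248384
S2-036,2,1,0,0,3,A,0.66000000000000003,0.55000000000000004,0.73999999999999999,0.751616
S2-037,2,3,0,0,1,S,0.65000000000000002,0.55000000000000004,0.55000000000000004,0.810886
S2-038,2,0,3,1,0,A,0.65000000000000002,0.55000000000000004,0.55000000000000004,0.189114
S2-039,2,0,1,3,0,S,0.55000000000000004,0.65000000000000002,0.55000000000000004,0.810886
S2-040,2,1,0,0,3,A,0.55000000000000004,0.65000000000000002,0.55000000000000004,0.189114
S2-041,2,3,0,0,1,S,0.66000000000000003,0.56000000000000005,0.56999999999999995,0.812581
S2-042,2,0,3,1,0,A,0.66000000000000003,0.56000000000000005,0.56999999999999995,0.187419
S2-043,2,0,1,3,0,S,0.56000000000000005,0.66000000000000003,0.56999999999999995,0.812581
S2-044,2,1,0,0,3,A,0.56000000000000005,0.66000000000000003,0.56999999999999995,0.187419
S2-045,2,3,0,0,1,S,0.66000000000000003,0.56999999999999995,0.56000000000000005,0.812581
S2-046,2,0,3,1,0,A,0.66000000000000003,0.56999999999999995,0.56000000000000005,0.187419
S2-047,2,0,1,3,0,S,0.56999999999999995,0.66000000000000003,0.56000000000000005,0.812581
S2-048,2,1,0,0,3,A,0.56999999999999995,0.66000000000000003,0.56000000000000005,0.187419
S2-049,2,3,0,0,1,S,0.69999999999999996,0.55000000000000004,0.55000000000000004,0.894783
S2-050,2,0,3,1,0,A,0.69999999999999996,0.55000000000000004,0.55000000000000004,0.105217
S2-051,2,0,1,3,0,S,0.55000000000000004,0.69999999999999996,0.55000000000000004,0.894783
S2-052,2,1,0,0,3,A,0.55000000000000004,0.69999999999999996,0.55000000000000004,0.105217
S2-053,2,3,0,0,1,S,0.69999999999999996,0.55000000000000004,0.56999999999999995,0.886891
S2-054,2,0,3,1,0,A,0.69999999999999996,0.55000000000000004,0.56999999999999995,0.113109
S2-055,2,0,1,3,0,S,0.55000000000000004,0.69999999999999996,0.56999999999999995,0.886891
S2-056,2,1,0,0,3,A,0.55000000000000004,0.69999999999999996,0.56999999999999995,0.113109
S2-057,2,3,0,0,1,S,0.69999999999999996,0.56999999999999995,0.55000000000000004,0.886891
S2-058,2,0,3,1,0,A,0.69999999999999996,0.56999999999999995,0.55000000000000004,0.113109
S2-059,2,0,1,3,0,S,0.56999999999999995,0.69999999999999996,0.55000000000000004,0.886891
S2-060,2,1,0,0,3,A,0.56999999999999995,0.69999999999999996,0.55000000000000004,0.113109
S2-061,2,3,0,0,1,S,0.56000000000000005,0.98999999999999999,0.59999999999999998,0.013693
S2-062,2,0,3,1,0,A,0.56000000000000005,0.98999999999999999,0.59999999999999998,0.986307
S2-063,2,0,1,3,0,S,0.98999999999999999,0.56000000000000005,0.59999999999999998,0.013693
S2-064,2,1,0,0,3,A,0.98999999999999999,0.56000000000000005,0.59999999999999998,0.986307
S2-065,2,3,0,0,1,S,0.55000000000000004,0.98999999999999999,0.65000000000000002,0.009833
S2-066,2,0,3,1,0,A,0.55000000000000004,0.98999999999999999,0.65000000000000002,0.990167
S2-067,2,0,1,3,0,S,0.98999999999999999,0.55000000000000004,0.65000000000000002,0.009833
S2-068,2,1,0,0,3,A,0.98999999999999999,0.55000000000000004,0.65000000000000002,0.990167
S2-069,2,3,0,0,1,S,0.56000000000000005,0.98999999999999999,0.62,0.012602
S2-070,2,0,3,1,0,A,0.56000000000000005,0.98999999999999999,0.62,0.987398
S2-071,2,0,1,3,0,S,0.98999999999999999,0.56000000000000005,0.62,0.012602
S2-072,2,1,0,0,3,A,0.98999999999999999,0.56000000000000005,0.62,0.987398
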