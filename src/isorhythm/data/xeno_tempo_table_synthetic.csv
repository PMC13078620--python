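species,group,tempo_hz,modality,medium
synthetic bird 01,bird,3.66,sound,air
synthetic bird 02,bird,5.01,sound,air
synthetic bird 03,bird,1.45,sound,air
synthetic bird 04,bird,0.53,sound,air
synthetic bird 05,bird,2.75,sound,air
synthetic bird 06,bird,0.59,sound,air
synthetic bird 07,bird,4.55,sound,air
synthetic bird 08,bird,5.56,sound,air
synthetic bird 09,bird,4.03,sound,air
synthetic bird 10,bird,1.58,sound,air
synthetic bat 01,bat,4.15,sound,air
synthetic bat 02,bat,2.76,sound,air
synthetic bat 03,bat,1.98,sound,air
synthetic bat 04,bat,4.29,sound,air
synthetic bat 05,bat,0.42,sound,air
synthetic bat 06,bat,1.31,sound,air
synthetic bat 07,bat,3.4,sound,air
synthetic bat 08,bat,1.46,sound,air
synthetic bat 09,bat,3.25,sound,air
synthetic bat 10,bat,3.5,sound,air
synthetic frog 01,frog,8.86,sound,air
synthetic frog 02,frog,1.78,sound,air
synthetic frog 03,frog,2.59,sound,air
synthetic frog 04,frog,1.9,sound,air
synthetic frog 05,frog,4.69,sound,air
synthetic frog 06,frog,6.55,sound,air
synthetic frog 07,frog,2.06,sound,air
synthetic frog 08,frog,9.06,sound,air
synthetic frog 09,frog,42.66,sound,air
synthetic frog 10,frog,6.1,sound,air
synthetic grasshopper 01,grasshopper,2.37,sound,air
synthetic grasshopper 02,grasshopper,4.68,sound,air
synthetic grasshopper 03,grasshopper,1.85,sound,air
synthetic grasshopper 04,grasshopper,4.64,sound,air
synthetic grasshopper 05,grasshopper,6.25,sound,air
synthetic grasshopper 06,grasshopper,4.74,sound,air
synthetic grasshopper 07,grasshopper,2.58,sound,air
synthetic grasshopper 08,grasshopper,0.8,sound,air
synthetic grasshopper 09,grasshopper,0.47,sound,air
synthetic grasshopper 10,grasshopper,14.32,sound,air
synthetic land mammal 01,land mammal,3.74,sound,air
synthetic land mammal 02,land mammal,2.02,sound,air
synthetic land mammal 03,land mammal,2.0,sound,air
synthetic land mammal 04,land mammal,4.3,sound,air
synthetic land mammal 05,land mammal,1.48,sound,air
synthetic land mammal 06,land mammal,6.72,sound,air
synthetic land mammal 07,land mammal,5.36,sound,air
synthetic land mammal 08,land mammal,23.59,sound,air
synthetic land mammal 09,land mammal,10.27,sound,air
synthetic land mammal 10,land mammal,1.21,sound,air
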