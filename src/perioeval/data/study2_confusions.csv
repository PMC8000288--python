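model,architecture,method,tn,fp,fn,tp,declared_n
ResNet_Nearest,resnet,nearest,19,33,3,49,104
ResNet_Bilinear,resnet,bilinear,26,26,2,50,104
ResNet_Bicubic,resnet,bicubic,38,14,13,39,104
ResNet_Lanczos,resnet,lanczos,49,3,27,25,104
ResNet_SRCNN,resnet,srcnn,33,19,5,47,104
ResNet_SRGAN,resnet,srgan,46,6,21,31,104
Inception_Nearest,inception,nearest,32,20,2,50,104
Inception_Bilinear,inception,bilinear,25,27,5,74,104
Inception_Bicubic,inception,bicubic,37,15,4,48,104
Inception_Lanczos,inception,lanczos,25,27,1,51,104
Inception_SRCNN,inception,srcnn,32,20,9,43,104
Inception_SRGAN,inception,srgan,36,16,10,42,104
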